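"""Radial Darcy inference of intra-tissue swelling pressure.

The probe membrane sits inside the tissue; water flows radially outward
through the membrane annulus (r1..r2) and into a perfused tissue annulus
(r2..r3).  With the probe filled with 0.15 mol/L NaCl (the bath salt), the
hydrostatic gradient measured negligible, and flow quasi-steady over the
5 min measurement, the flux obeys

    q = 2 pi L K_total / ln(r3/r1) * (pi_tissue - pi_probe)

where K_total is the log-weighted harmonic average of membrane and tissue
hydraulic permeabilities, r3 follows from the perfused-volume balance
pi L (r3^2 - r2^2) = q t, and the tissue permeability depends on the radial
stretch ratio lambda = (m_f/m_0)^(1/3) through a strain-dependent law
calibrated for bovine nucleus pulposus in confined compression.

Inference is sequential: measured q fixes r3, then K_total, then the
swelling pressure Delta_pi = pi_tissue - pi_probe, then the absolute tissue
osmotic pressure and osmolality.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .constants import PhysicalConstants
from .errors import GeometryError, InvalidInputError, ModelError
from .instrument_model import CalibrationTable, ProbeGeometry

__all__ = [
    "TissueFluxRecord", "SwellingResult", "perfusion_radius",
    "radial_stretch", "tissue_permeability", "effective_total_permeability",
    "swelling_pressure_from_flux", "osmolality_from_pressure",
    "pressure_from_osmolality", "infer_sample", "infer_cohort",
    "TISSUE_PERMEABILITY_REF", "perfused_water_fraction",
]

#: Reference hydraulic permeability of unstrained bovine NP tissue,
#: m^4 N^-1 s^-1 (the lambda = 1 value of the strain-dependent law).
TISSUE_PERMEABILITY_REF = 1.59e-15


@dataclass(frozen=True)
class TissueFluxRecord:
    """One tissue sample's flux measurement set and masses (SI).

    m0 is the wet mass at excision, mf after osmotic equilibration, and
    post_flux_wet_mass after the three flux measurements; dry_mass after
    lyophilization.  Up to three replicate fluxes are averaged before
    inference.
    """

    sample_id: str
    probe_id: str
    applied_pressure: float            # Pa
    excision_wet_mass: float           # kg (m0)
    post_equilibration_wet_mass: float  # kg (mf)
    post_flux_wet_mass: float          # kg
    dry_mass: float                    # kg
    triplicate_fluxes: tuple[float, ...]
    perfusion_time: float = 300.0      # s

    def __post_init__(self) -> None:
        masses = (self.excision_wet_mass, self.post_equilibration_wet_mass,
                  self.post_flux_wet_mass, self.dry_mass)
        if min(masses) <= 0:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: all masses must be > 0")
        if self.dry_mass >= self.post_flux_wet_mass:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: dry mass must be below the "
                "post-flux wet mass")
        fluxes = tuple(float(q) for q in self.triplicate_fluxes)
        if not 1 <= len(fluxes) <= 3:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: expected 1-3 replicate fluxes")
        if self.perfusion_time <= 0:
            raise InvalidInputError("perfusion time must be > 0")
        object.__setattr__(self, "triplicate_fluxes", fluxes)

    @property
    def mean_flux(self) -> float:
        """Arithmetic mean of replicate fluxes, m^3/s."""
        return sum(self.triplicate_fluxes) / len(self.triplicate_fluxes)


@dataclass(frozen=True)
class SwellingResult:
    """Per-sample inference output."""

    sample_id: str
    applied_pressure: float    # Pa
    mean_flux: float           # m^3/s
    perfusion_radius: float    # m (r3)
    stretch_ratio: float       # lambda
    k_tissue: float            # m^4 N^-1 s^-1
    k_membrane: float          # m^4 N^-1 s^-1
    k_total: float             # m^4 N^-1 s^-1
    delta_pi: float            # Pa, pi_tissue - pi_probe (0.15 M bath)
    pi_tissue_absolute: float  # Pa
    osmolality: float          # mOsm/kg H2O
    hydration: float           # g H2O / g dry weight (post flux)
    perfused_water_fraction: float  # perfused mass / TTW mass


def perfusion_radius(q: float, t: float, geometry: ProbeGeometry) -> float:
    """Outer radius r3 (m) of the perfused tissue annulus.

    Volume balance: the cylindrical annulus pi L (r3^2 - r2^2) holds exactly
    the perfused fluid volume q*t (no redistribution on the 5 min
    timescale).
    """
    if q < 0:
        raise InvalidInputError(f"negative flux {q}: positive means into "
                                "the tissue")
    if t <= 0:
        raise InvalidInputError("perfusion time must be > 0")
    r2 = geometry.outer_membrane_radius
    return math.sqrt(q * t / (math.pi * geometry.membrane_length) + r2 * r2)


def radial_stretch(m0: float, mf: float,
                   constants: PhysicalConstants | None = None) -> float:
    """Radial stretch ratio lambda = (mf/m0)^(1/3).

    Pressure is applied isotropically by equilibrium dialysis, so the
    tissue's radius change stands in for the 1D stretch of the permeability
    law; radii come from wet masses assuming spherical geometry at constant
    tissue density (the density cancels in the ratio).
    """
    if m0 <= 0 or mf <= 0:
        raise InvalidInputError("masses must be > 0")
    return (mf / m0) ** (1.0 / 3.0)


def tissue_permeability(lam: float) -> float:
    """Strain-dependent hydraulic permeability of NP tissue, m^4 N^-1 s^-1.

    K(lambda) = 1.59e-15 * ((lambda - 0.2)/0.8)^1.13
                * exp(-0.02 (lambda^2 - 1)^2)

    valid for lambda > 0.2 (permeability vanishes as the pore space closes);
    below that the law is non-physical and a ModelError is raised rather
    than clamping.
    """
    if lam <= 0.2:
        raise ModelError(
            f"stretch ratio {lam} <= 0.2: tissue permeability law undefined "
            "(pore space closed)")
    return (TISSUE_PERMEABILITY_REF * ((lam - 0.2) / 0.8) ** 1.13
            * math.exp(-0.02 * (lam * lam - 1.0) ** 2))


def effective_total_permeability(k_mem: float, k_tissue: float,
                                 r1: float, r2: float, r3: float) -> float:
    """Log-weighted harmonic average permeability of the membrane annulus
    (r1..r2) in series with the perfused tissue annulus (r2..r3):

        K_total = ln(r3/r1) / [ ln(r2/r1)/K_mem + ln(r3/r2)/K_tissue ]
    """
    if not 0 < r1 < r2:
        raise GeometryError(f"require 0 < r1 < r2, got r1={r1}, r2={r2}")
    if r3 < r2:
        raise GeometryError(f"perfusion radius r3={r3} below membrane outer "
                            f"radius r2={r2}")
    if k_mem <= 0 or k_tissue <= 0:
        raise ModelError("permeabilities must be > 0")
    if r3 == r2:
        return k_mem
    resistance = (math.log(r2 / r1) / k_mem + math.log(r3 / r2) / k_tissue)
    return math.log(r3 / r1) / resistance


def swelling_pressure_from_flux(q: float, geometry: ProbeGeometry,
                                k_total: float, r3: float,
                                hydrostatic_offset: float = 0.0) -> float:
    """Swelling pressure Delta_pi = pi_tissue - pi_probe (Pa) from flux.

    Delta_pi = q ln(r3/r1) / (2 pi L K_total) - hydrostatic_offset.  The
    hydrostatic term is zero by default (measured three orders of magnitude
    below the osmotic gradient); a transducer-paired measurement can supply
    it explicitly.
    """
    if k_total <= 0:
        raise ModelError(f"non-positive total permeability {k_total}")
    if r3 <= geometry.inner_membrane_radius:
        raise GeometryError("perfusion radius must exceed inner membrane "
                            "radius")
    return (q * math.log(r3 / geometry.inner_membrane_radius)
            / (2.0 * math.pi * geometry.membrane_length * k_total)
            - hydrostatic_offset)


def osmolality_from_pressure(delta_pi: float,
                             constants: PhysicalConstants | None = None
                             ) -> float:
    """Absolute tissue osmolality (mOsm/kg H2O) from the swelling pressure
    relative to the 0.15 mol/L NaCl bath: (Delta_pi + pi_bath) / RT, with
    mol/m^3 identified with mOsm/kg H2O for dilute aqueous solutions."""
    constants = constants or PhysicalConstants()
    osm = (delta_pi + constants.bath_osmotic_pressure) / constants.rt
    if osm < 0:
        raise ModelError(
            f"swelling pressure {delta_pi} Pa implies negative osmolality")
    return osm


def pressure_from_osmolality(osmolality: float,
                             constants: PhysicalConstants | None = None
                             ) -> float:
    """Inverse of :func:`osmolality_from_pressure`: swelling pressure (Pa)
    relative to the bath for a given absolute osmolality (mOsm/kg H2O)."""
    constants = constants or PhysicalConstants()
    if osmolality < 0:
        raise InvalidInputError("osmolality must be >= 0")
    return osmolality * constants.rt - constants.bath_osmotic_pressure


def perfused_water_fraction(q: float, t: float, post_flux_wet: float,
                            dry: float,
                            constants: PhysicalConstants | None = None
                            ) -> float:
    """Mass of water perfused during the measurement as a fraction of total
    tissue water — a sanity check that the measurement itself negligibly
    alters hydration (should be well below 1 %)."""
    constants = constants or PhysicalConstants()
    ttw = post_flux_wet - dry
    if ttw <= 0:
        raise InvalidInputError("post-flux wet mass must exceed dry mass")
    return q * t * 1000.0 / ttw  # water density 1000 kg/m^3


def infer_sample(record: TissueFluxRecord,
                 calibration: CalibrationTable,
                 constants: PhysicalConstants | None = None,
                 geometry: ProbeGeometry | None = None,
                 hydrostatic_offset: float = 0.0) -> SwellingResult:
    """Full inference chain for one sample.

    Averages the replicate fluxes, then chains radial stretch ->
    strain-dependent tissue permeability -> perfusion radius -> effective
    permeability -> swelling pressure -> osmolality.
    """
    constants = constants or PhysicalConstants()
    geometry = geometry or ProbeGeometry()

    q = record.mean_flux
    cal = calibration.lookup(record.probe_id, record.applied_pressure)
    lam = radial_stretch(record.excision_wet_mass,
                         record.post_equilibration_wet_mass)
    k_tis = tissue_permeability(lam)
    r3 = perfusion_radius(q, record.perfusion_time, geometry)
    k_tot = effective_total_permeability(
        cal.hydraulic_permeability, k_tis,
        geometry.inner_membrane_radius, geometry.outer_membrane_radius, r3)
    delta_pi = swelling_pressure_from_flux(
        q, geometry, k_tot, r3, hydrostatic_offset=hydrostatic_offset)
    osm = osmolality_from_pressure(delta_pi, constants)
    hydration = ((record.post_flux_wet_mass - record.dry_mass)
                 / record.dry_mass)
    return SwellingResult(
        sample_id=record.sample_id,
        applied_pressure=record.applied_pressure,
        mean_flux=q,
        perfusion_radius=r3,
        stretch_ratio=lam,
        k_tissue=k_tis,
        k_membrane=cal.hydraulic_permeability,
        k_total=k_tot,
        delta_pi=delta_pi,
        pi_tissue_absolute=delta_pi + constants.bath_osmotic_pressure,
        osmolality=osm,
        hydration=hydration,
        perfused_water_fraction=perfused_water_fraction(
            q, record.perfusion_time, record.post_flux_wet_mass,
            record.dry_mass, constants),
    )


def infer_cohort(records: Sequence[TissueFluxRecord],
                 calibration: CalibrationTable,
                 constants: PhysicalConstants | None = None,
                 geometry: ProbeGeometry | None = None) -> list[SwellingResult]:
    """Run :func:`infer_sample` over a cohort, preserving input order."""
    return [infer_sample(r, calibration, constants, geometry)
            for r in records]
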