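"""Gibbs-Donnan ionic swelling from measured intra-tissue sodium.

The tissue's proteoglycans carry a fixed negative charge density (FCD).  At
equilibrium with a NaCl bath of concentration c_ext, the mobile ions
distribute so that the ion products match (c_na_int * c_cl_int = c_ext^2)
and the tissue stays electroneutral (c_na_int = c_cl_int + c_f).  Measuring
intra-tissue sodium (ICP-OES) normalized to total tissue water (TTW)
therefore determines the partition coefficient k = c_na_int/c_ext, the FCD
c_f = k c_ext - c_ext/k, intra-tissue chloride, total ions, the ionic
swelling pressure

    Delta_pi_ion = phi R T (sqrt(c_f^2 + 4 c_ext^2) - 2 c_ext)

and the tissue osmolality phi * (total ions).  All concentrations per litre
of TTW; mEq/g TTW is numerically identical for a monovalent ion at water
density.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import sqrt

from .constants import PhysicalConstants
from .errors import InvalidInputError, ModelError

__all__ = [
    "IcpOesRecord", "DonnanState", "hydration", "sodium_concentration",
    "partition_coefficient", "fixed_charge_density", "intratissue_chloride",
    "total_ion_concentration", "ionic_swelling_pressure",
    "osmolality_from_ions", "donnan_fraction", "donnan_state",
    "bath_drift_percent",
]


@dataclass(frozen=True)
class IcpOesRecord:
    """ICP-OES sodium measurement for one sample.

    sodium_mass is the total moles of Na in the digested aliquot;
    aliquot_dry_mass the dry mass digested (defaults to the whole sample's
    dry mass, i.e. full digestion); sample wet/dry masses give the TTW
    volume the concentration is normalized to.
    """

    sample_id: str
    sodium_mass: float       # mol
    sample_wet_mass: float   # kg (post-flux wet weight)
    sample_dry_mass: float   # kg
    aliquot_dry_mass: float | None = None  # kg; None -> whole sample

    def __post_init__(self) -> None:
        if min(self.sodium_mass, self.sample_wet_mass,
               self.sample_dry_mass) < 0:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: masses must be >= 0")
        if self.sample_wet_mass <= self.sample_dry_mass:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: wet mass must exceed dry mass")
        aliquot = self.aliquot_dry_mass
        if aliquot is not None and not 0 < aliquot <= self.sample_dry_mass:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: aliquot dry mass must be in "
                "(0, sample dry mass]")

    @property
    def total_sodium(self) -> float:
        """Moles of Na in the whole sample (aliquot scaled by dry mass)."""
        if self.aliquot_dry_mass is None:
            return self.sodium_mass
        return self.sodium_mass * self.sample_dry_mass / self.aliquot_dry_mass


@dataclass(frozen=True)
class DonnanState:
    """Ionic state of one sample at Gibbs-Donnan equilibrium."""

    sample_id: str
    c_na_int: float              # mol/L TTW
    c_cl_int: float              # mol/L TTW
    fcd: float                   # mEq/g TTW == mol/L TTW
    total_ions: float            # mol/L TTW
    ionic_swelling_pressure: float  # Pa
    osmolality: float            # mOsm/kg H2O
    hydration: float             # g H2O / g dry weight
    donnan_consistent: bool = True  # False when measured c_na < c_ext


def hydration(post_flux_wet: float, dry: float) -> float:
    """Tissue hydration on a TTW basis: (wet - dry)/dry, g H2O/g dry."""
    if dry <= 0:
        raise InvalidInputError("dry mass must be > 0")
    if post_flux_wet < dry:
        raise InvalidInputError("wet mass below dry mass")
    return (post_flux_wet - dry) / dry


def sodium_concentration(na_mass: float, wet: float, dry: float) -> float:
    """Intra-tissue sodium (mol/L of TTW) from total sodium moles and the
    TTW volume (wet - dry) at water density 1000 kg/m^3."""
    if wet <= dry:
        raise InvalidInputError("wet mass must exceed dry mass")
    if na_mass < 0:
        raise InvalidInputError("sodium mass must be >= 0")
    ttw_litres = (wet - dry) / 1000.0 * 1000.0  # kg -> m^3 -> L
    return na_mass / ttw_litres


def _check_donnan(c_na_int: float, c_ext: float) -> bool:
    """True when the measurement is Donnan-consistent (c_na_int >= c_ext);
    otherwise warn (negative FCD implied) and let the caller proceed."""
    if c_na_int <= 0 or c_ext <= 0:
        raise InvalidInputError("concentrations must be > 0")
    if c_na_int < c_ext:
        warnings.warn(
            f"intra-tissue sodium {c_na_int:.4g} mol/L below bath "
            f"{c_ext:.4g} mol/L: implies negative FCD (measurement noise?); "
            "proceeding with k < 1", stacklevel=3)
        return False
    return True


def partition_coefficient(c_na_int: float, c_ext: float) -> float:
    """Donnan partition coefficient k = c_na_int/c_ext (>= 1 for a tissue
    with non-negative FCD)."""
    _check_donnan(c_na_int, c_ext)
    return c_na_int / c_ext


def fixed_charge_density(c_na_int: float, c_ext: float) -> float:
    """FCD from electroneutrality + ion product:
    c_f = k c_ext - c_ext/k = c_na_int - c_ext^2/c_na_int (mol/L TTW)."""
    _check_donnan(c_na_int, c_ext)
    return c_na_int - c_ext * c_ext / c_na_int


def intratissue_chloride(c_na_int: float, c_ext: float) -> float:
    """Intra-tissue chloride via the ion product: c_cl = c_ext^2/c_na_int."""
    _check_donnan(c_na_int, c_ext)
    return c_ext * c_ext / c_na_int


def total_ion_concentration(c_na_int: float, c_ext: float) -> float:
    """Total mobile ions: c_na_int + c_ext^2/c_na_int (mol/L TTW)."""
    _check_donnan(c_na_int, c_ext)
    return c_na_int + c_ext * c_ext / c_na_int


def ionic_swelling_pressure(c_f: float,
                            constants: PhysicalConstants | None = None
                            ) -> float:
    """Ionic (Donnan) swelling pressure over the bath, Pa:

    Delta_pi_ion = phi R T (sqrt(c_f^2 + 4 c_ext^2) - 2 c_ext)

    with the same osmotic coefficient applied inside and outside, and
    concentrations in mol/m^3.
    """
    if c_f < 0:
        raise InvalidInputError(f"FCD must be >= 0, got {c_f}")
    constants = constants or PhysicalConstants()
    cf = c_f * 1000.0                          # mol/L -> mol/m^3
    cext = constants.bath_concentration * 1000.0
    return (constants.osmotic_coefficient * constants.rt
            * (sqrt(cf * cf + 4.0 * cext * cext) - 2.0 * cext))


def osmolality_from_ions(total_ions: float,
                         phi: float = 0.93) -> float:
    """Tissue osmolality (mOsm/kg H2O) from total mobile ions (mol/L TTW):
    phi * total_ions * 1000."""
    if total_ions < 0:
        raise InvalidInputError("total ion concentration must be >= 0")
    return phi * total_ions * 1000.0


def donnan_fraction(osm_ion: float, osm_flux: float,
                    constants: PhysicalConstants | None = None) -> float:
    """Fraction of the flux-based swelling pressure accounted for by Donnan
    (ionic) swelling: (osm_ion - osm_bath)/(osm_flux - osm_bath).

    Equals the ratio of the two swelling pressures, since both share the
    RT factor.  Undefined when the flux osmolality does not exceed the
    bath's.
    """
    constants = constants or PhysicalConstants()
    bath = constants.bath_osmolarity
    if osm_flux <= bath:
        raise ModelError(
            f"flux osmolality {osm_flux} does not exceed bath osmolality "
            f"{bath}: Donnan fraction undefined")
    return (osm_ion - bath) / (osm_flux - bath)


def donnan_state(record: IcpOesRecord,
                 constants: PhysicalConstants | None = None) -> DonnanState:
    """Full Gibbs-Donnan chain for one ICP-OES record."""
    constants = constants or PhysicalConstants()
    c_ext = constants.bath_concentration
    c_na = sodium_concentration(record.total_sodium, record.sample_wet_mass,
                                record.sample_dry_mass)
    consistent = _check_donnan(c_na, c_ext)
    c_cl = c_ext * c_ext / c_na
    c_f = c_na - c_cl
    total = c_na + c_cl
    pressure = ionic_swelling_pressure(max(c_f, 0.0), constants)
    return DonnanState(
        sample_id=record.sample_id,
        c_na_int=c_na,
        c_cl_int=c_cl,
        fcd=c_f,
        total_ions=total,
        ionic_swelling_pressure=pressure,
        osmolality=osmolality_from_ions(total,
                                        constants.osmotic_coefficient),
        hydration=hydration(record.sample_wet_mass, record.sample_dry_mass),
        donnan_consistent=consistent,
    )


def bath_drift_percent(c_start: float, c_end: float,
                       warn_threshold: float = 1.0) -> float:
    """Percent change of bath concentration over equilibration; warns above
    ``warn_threshold`` % since the Donnan equations assume a fixed bath."""
    if c_start <= 0:
        raise InvalidInputError("starting bath concentration must be > 0")
    drift = abs(c_end - c_start) / c_start * 100.0
    if drift > warn_threshold:
        warnings.warn(
            f"bath concentration drifted {drift:.2f} % during "
            "equilibration; fixed-bath Donnan assumption questionable",
            stacklevel=2)
    return drift
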