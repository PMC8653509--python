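"""Micro-osmometer probe hardware model and membrane calibration.

A microdialysis probe (cylindrical semi-permeable membrane on a needle,
connected to fine tubing with a visible water/air meniscus) is calibrated by
immersing it in polyethylene-glycol (PEG) solutions of known osmotic
pressure.  The meniscus displacement rate gives the volumetric water flux
through the membrane, and the radial Darcy law for the membrane annulus then
yields a hydraulic membrane permeability

    K_mem = q * ln(r2/r1) / (2 pi L * pi_PEG)        [m^4 N^-1 s^-1]

Everything downstream works in this single hydraulic permeability
K = k/mu (intrinsic permeability over viscosity); viscosity never re-enters.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (CalibrationLookupError, ConfigurationError,
                     GeometryError, InvalidInputError)

__all__ = [
    "ProbeGeometry", "DisplacementSeries", "CalibrationRecord",
    "MembraneCalibration", "CalibrationTable", "VirialCoefficients",
    "DEFAULT_VIRIAL_COEFFICIENTS", "displacement_to_flux",
    "peg_osmotic_pressure", "membrane_permeability_from_calibration",
    "membrane_flux", "calibrate",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Fixed instrument dimensions (SI).

    Defaults are the production probe: 6 kDa polyethersulfone membrane with
    inner radius 0.113 mm (microscope), outer radius 0.12 mm (manufacturer),
    length 5 mm, and 0.38 mm bore tubing carrying the meniscus.
    """

    inner_membrane_radius: float = 0.113e-3
    outer_membrane_radius: float = 0.12e-3
    membrane_length: float = 5e-3
    tubing_inner_diameter: float = 0.38e-3

    def __post_init__(self) -> None:
        if not 0 < self.inner_membrane_radius < self.outer_membrane_radius:
            raise GeometryError(
                "require 0 < inner radius < outer radius, got "
                f"r1={self.inner_membrane_radius}, "
                f"r2={self.outer_membrane_radius}")
        if self.membrane_length <= 0 or self.tubing_inner_diameter <= 0:
            raise GeometryError("membrane length and tubing bore must be > 0")

    @property
    def r1(self) -> float:
        return self.inner_membrane_radius

    @property
    def r2(self) -> float:
        return self.outer_membrane_radius

    @property
    def tubing_cross_section(self) -> float:
        """Cross-sectional area of the meniscus tubing, m^2."""
        return math.pi * (self.tubing_inner_diameter / 2.0) ** 2

    @property
    def membrane_log_ratio(self) -> float:
        """ln(r2/r1), the geometric factor of the membrane annulus."""
        return math.log(self.outer_membrane_radius
                        / self.inner_membrane_radius)


@dataclass(frozen=True)
class DisplacementSeries:
    """Meniscus position along the tubing sampled over time.

    times are seconds (strictly increasing, >= 2 frames), positions are
    metres; sign convention: positions increase as fluid leaves the tubing
    toward the membrane (flux into tissue/bath is positive).
    """

    times: tuple[float, ...]
    positions: tuple[float, ...]

    def __init__(self, times: Sequence[float], positions: Sequence[float]):
        t = tuple(float(v) for v in times)
        p = tuple(float(v) for v in positions)
        if len(t) < 2 or len(p) != len(t):
            raise InvalidInputError(
                "displacement series needs >= 2 (time, position) frames")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    def slope(self, method: str = "ols") -> float:
        """Meniscus displacement rate, m/s.

        method='ols' fits ordinary least squares over all frames (default);
        method='endpoints' uses a two-point finite difference.
        """
        if method == "endpoints":
            return ((self.positions[-1] - self.positions[0])
                    / (self.times[-1] - self.times[0]))
        if method != "ols":
            raise InvalidInputError(f"unknown slope method {method!r}")
        t = np.asarray(self.times)
        p = np.asarray(self.positions)
        tc = t - t.mean()
        return float(tc @ (p - p.mean()) / (tc @ tc))


@dataclass(frozen=True)
class CalibrationRecord:
    """One calibration observation: a probe in a PEG bath of known (or
    computable) osmotic pressure, with its meniscus displacement series."""

    probe_id: str
    series: DisplacementSeries
    peg_mass_concentration: float | None = None   # g/mL
    applied_osmotic_pressure: float | None = None  # Pa

    def __post_init__(self) -> None:
        if (self.peg_mass_concentration is None
                and self.applied_osmotic_pressure is None):
            raise ConfigurationError(
                f"calibration record for probe {self.probe_id!r} has neither "
                "a PEG concentration nor an applied pressure")

    def pressure(self, coeffs: "VirialCoefficients | None" = None) -> float:
        """Resolve the applied osmotic pressure, Pa."""
        if self.applied_osmotic_pressure is not None:
            return self.applied_osmotic_pressure
        if coeffs is None:
            raise ConfigurationError(
                "PEG concentration given but no virial coefficients supplied")
        return peg_osmotic_pressure(self.peg_mass_concentration, coeffs)


@dataclass(frozen=True)
class MembraneCalibration:
    """Fitted hydraulic permeability of one probe membrane at one applied
    pressure (membrane permeability is itself pressure dependent)."""

    probe_id: str
    applied_pressure: float        # Pa
    hydraulic_permeability: float  # m^4 N^-1 s^-1
    flux: float | None = None      # the calibration flux, m^3/s

    def __post_init__(self) -> None:
        if self.hydraulic_permeability < 0:
            raise InvalidInputError("membrane permeability must be >= 0")


@dataclass(frozen=True)
class VirialCoefficients:
    """Polynomial mapping of PEG mass concentration c (g/mL) to osmotic
    pressure: pi(c) = sum_k a_k c^k  with a_0 = 0 (pure solvent exerts none).

    coefficients = (a1, a2, a3, ...), units Pa per (g/mL)^k.  The resulting
    pressure must be non-negative and non-decreasing over 0-0.25 g/mL.
    """

    coefficients: tuple[float, ...]

    def __init__(self, coefficients: Sequence[float]):
        coefs = tuple(float(a) for a in coefficients)
        if not coefs:
            raise ConfigurationError("at least one virial coefficient needed")
        c = np.linspace(0.0, 0.25, 251)
        p = np.polyval(list(reversed(coefs)) + [0.0], c)
        if (p < -1e-9).any() or (np.diff(p) < -1e-9).any():
            raise ConfigurationError(
                "virial coefficients give a negative or decreasing pressure "
                "on 0-0.25 g/mL")
        object.__setattr__(self, "coefficients", coefs)

    def __call__(self, c: float) -> float:
        return peg_osmotic_pressure(c, self)


#: Placeholder virial set for 20 kDa PEG at 25 degC, fitted through the five
#: (concentration, applied pressure) pairs used in the tissue experiments
#: (0.05-0.25 g/mL -> 0.03-0.57 MPa).  NON-AUTHORITATIVE: the published
#: virial coefficients are in an external handbook; supply your own via
#: config for quantitative calibration work.
DEFAULT_VIRIAL_COEFFICIENTS = VirialCoefficients(
    (195749.70484061, 7766233.76623379, 2314049.58677682))


def displacement_to_flux(series: DisplacementSeries,
                         geometry: ProbeGeometry,
                         method: str = "ols") -> float:
    """Convert a meniscus displacement series to volumetric flux, m^3/s.

    The displacement rate (least-squares slope of position vs time) is
    multiplied by the tubing cross-sectional area.  Positive flux means
    fluid leaving the tubing into the tissue or bath.
    """
    return series.slope(method=method) * geometry.tubing_cross_section


def peg_osmotic_pressure(c: float, coeffs: VirialCoefficients) -> float:
    """Osmotic pressure (Pa) of a PEG solution at mass concentration
    c (g/mL), via the virial polynomial."""
    if c is None or c < 0:
        raise InvalidInputError(f"PEG concentration must be >= 0, got {c}")
    if c > 0.30:
        raise InvalidInputError(
            f"PEG concentration {c} g/mL outside the calibrated range (<=0.30)")
    return float(sum(a * c ** (k + 1)
                     for k, a in enumerate(coeffs.coefficients)))


def membrane_permeability_from_calibration(q: float,
                                           geometry: ProbeGeometry,
                                           pi_peg: float) -> float:
    """Invert the radial Darcy law for the membrane annulus alone.

    K_mem = q ln(r2/r1) / (2 pi L pi_PEG).  Requires pi_peg > 0 and q >= 0
    (flux out of the probe, i.e. into the bath, is positive).
    """
    if pi_peg <= 0:
        raise InvalidInputError(f"applied osmotic pressure must be > 0, "
                                f"got {pi_peg}")
    if q < 0:
        raise InvalidInputError(
            f"negative calibration flux {q}: fluid should flow out of the "
            "probe under PEG load (check the sign convention)")
    return (q * geometry.membrane_log_ratio
            / (2.0 * math.pi * geometry.membrane_length * pi_peg))


def membrane_flux(k_mem: float, geometry: ProbeGeometry,
                  delta_pi: float) -> float:
    """Forward membrane-only Darcy flux (m^3/s) for permeability k_mem under
    osmotic pressure difference delta_pi — the inverse of
    :func:`membrane_permeability_from_calibration`."""
    return (2.0 * math.pi * geometry.membrane_length * k_mem * delta_pi
            / geometry.membrane_log_ratio)


def calibrate(records: Sequence[CalibrationRecord],
              geometry: ProbeGeometry | None = None,
              coeffs: VirialCoefficients | None = None,
              method: str = "ols") -> "CalibrationTable":
    """Fit a membrane permeability for every calibration record and collect
    them in a lookup table keyed on (probe_id, applied pressure)."""
    geometry = geometry or ProbeGeometry()
    entries = []
    for rec in records:
        pi_peg = rec.pressure(coeffs)
        q = displacement_to_flux(rec.series, geometry, method=method)
        k = membrane_permeability_from_calibration(q, geometry, pi_peg)
        entries.append(MembraneCalibration(rec.probe_id, pi_peg, k, flux=q))
    return CalibrationTable(entries)


@dataclass
class CalibrationTable:
    """Lookup of membrane calibrations keyed on (probe_id, applied pressure).

    Membrane permeability depends on the applied pressure, so lookups are
    exact on pressure when possible and fall back to the nearest calibrated
    pressure for that probe with a warning.  Probes whose permeability sits
    far outside the cohort spread can be flagged (not excluded) with
    :meth:`outlier_flags`.
    """

    entries: list[MembraneCalibration] = field(default_factory=list)

    def lookup(self, probe_id: str, applied_pressure: float,
               rel_tol: float = 1e-6) -> MembraneCalibration:
        mine = [e for e in self.entries if e.probe_id == probe_id]
        if not mine:
            raise CalibrationLookupError(
                f"no calibration for probe {probe_id!r}")
        exact = [e for e in mine
                 if math.isclose(e.applied_pressure, applied_pressure,
                                 rel_tol=rel_tol, abs_tol=1.0)]
        if exact:
            return exact[0]
        best = min(mine, key=lambda e: abs(e.applied_pressure
                                           - applied_pressure))
        warnings.warn(
            f"probe {probe_id!r} not calibrated at "
            f"{applied_pressure:.3g} Pa; using nearest calibrated pressure "
            f"{best.applied_pressure:.3g} Pa", stacklevel=2)
        return best

    def outlier_flags(self, n_mad: float = 5.0) -> dict[str, bool]:
        """Flag probes whose median permeability is more than ``n_mad``
        scaled median absolute deviations from the cohort median."""
        import statistics
        per_probe: dict[str, list[float]] = {}
        for e in self.entries:
            per_probe.setdefault(e.probe_id, []).append(
                e.hydraulic_permeability)
        med = {p: statistics.median(v) for p, v in per_probe.items()}
        if len(med) < 3:
            return {p: False for p in med}
        values = list(med.values())
        center = statistics.median(values)
        mad = statistics.median([abs(v - center) for v in values]) or 1e-30
        return {p: abs(v - center) / (1.4826 * mad) > n_mad
                for p, v in med.items()}
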