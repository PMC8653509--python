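"""Forward simulator for the micro-osmometer experiment.

Emulates the full study design — five applied pressures (equilibrium
dialysis in PEG), five tissue samples per pressure, per-probe membrane
calibration, triplicate flux readings, and ICP-OES sodium — so the entire
inference pipeline can be exercised end-to-end without any laboratory data.

Ground truth ties the tissue swelling pressure exactly to the applied
pressure (the equilibrium the method validates): the generating osmolality
is bath + P/RT, and intra-tissue sodium follows from the Donnan ion
product.  Deviations of recovered values from truth therefore measure
pipeline noise only.

The forward flux problem is implicit — the perfusion radius depends on the
flux and vice versa — and is solved by bracketed root finding; the
inference chain in :mod:`osmoflux.darcy_inference` is its exact inverse in
the noise-free limit.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import PhysicalConstants
from .darcy_inference import (effective_total_permeability, perfusion_radius,
                              tissue_permeability)
from .errors import ConfigurationError, InvalidInputError, SolverError
from .instrument_model import ProbeGeometry, membrane_flux

__all__ = ["SimulationConfig", "SimulatedCohort", "forward_flux",
           "simulate_cohort"]

#: Applied osmotic pressures of the experimental design, Pa
#: (5/10/15/20/25 % g/mL 20 kDa PEG).
DEFAULT_PRESSURES = (0.03e6, 0.10e6, 0.21e6, 0.37e6, 0.57e6)

#: PEG mass concentrations (g/mL) paired with DEFAULT_PRESSURES.
DEFAULT_PEG_CONCENTRATIONS = (0.05, 0.10, 0.15, 0.20, 0.25)

#: Hydration (g H2O / g dry) anchor line endpoints vs applied pressure:
#: 4.96 at 0.03 MPa down to 1.64 at 0.57 MPa.
_HYDRATION_ANCHORS = ((0.03e6, 4.96), (0.57e6, 1.64))

#: Hydration of freshly excised (unloaded) tissue, g H2O / g dry weight —
#: slightly above the lowest-pressure equilibrated value, so stretch ratios
#: stay near 1 at low loads.
EXCISION_HYDRATION = 5.2

#: True membrane hydraulic permeability anchors (Pa -> m^4 N^-1 s^-1):
#: decreasing with applied pressure.  The scale is set so the water
#: perfused in a 5 min reading stays a small fraction (~0.1-0.2 %) of the
#: sample's total tissue water.
_KMEM_ANCHORS = ((0.03e6, 2.0e-18), (0.57e6, 0.8e-18))


def _interp_line(p: float, anchors) -> float:
    (x0, y0), (x1, y1) = anchors
    return y0 + (y1 - y0) * (p - x0) / (x1 - x0)


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise parameters of a synthetic cohort.

    Noise is multiplicative lognormal with the given relative SDs (a
    stand-in chosen to reproduce cohort-scale group SDs; only group-level
    spreads of the real experiment are known).
    """

    applied_pressures: tuple[float, ...] = DEFAULT_PRESSURES
    peg_concentrations: tuple[float, ...] = DEFAULT_PEG_CONCENTRATIONS
    samples_per_group: int = 5
    true_membrane_permeabilities: tuple[float, ...] | None = None
    flux_rel_sd: float = 0.05
    sodium_rel_sd: float = 0.08
    mass_rel_sd: float = 0.005
    mean_excision_mass: float = 0.20e-3   # kg
    excision_mass_rel_sd: float = 0.15
    perfusion_time: float = 300.0         # s
    n_frames: int = 6                     # meniscus images (t = 0..5 min)
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.applied_pressures
        if not p or any(x <= 0 for x in p) or any(
                b <= a for a, b in zip(p, p[1:])):
            raise ConfigurationError(
                "applied pressures must be positive and strictly increasing")
        if len(self.peg_concentrations) != len(p):
            raise ConfigurationError(
                "need one PEG concentration per applied pressure")
        if self.samples_per_group < 0:
            raise ConfigurationError("samples_per_group must be >= 0")
        if min(self.flux_rel_sd, self.sodium_rel_sd, self.mass_rel_sd,
               self.excision_mass_rel_sd) < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        km = self.true_membrane_permeabilities
        if km is not None and (len(km) != len(p) or any(k <= 0 for k in km)):
            raise ConfigurationError(
                "need one positive membrane permeability per pressure")

    def membrane_permeability(self, pressure: float) -> float:
        """True membrane permeability for the probe used at ``pressure``."""
        if self.true_membrane_permeabilities is not None:
            i = self.applied_pressures.index(pressure)
            return self.true_membrane_permeabilities[i]
        return _interp_line(pressure, _KMEM_ANCHORS)

    def digest(self) -> str:
        payload = {k: getattr(self, k) for k in (
            "applied_pressures", "peg_concentrations", "samples_per_group",
            "true_membrane_permeabilities", "flux_rel_sd", "sodium_rel_sd",
            "mass_rel_sd", "mean_excision_mass", "excision_mass_rel_sd",
            "perfusion_time", "n_frames", "seed")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def forward_flux(delta_pi: float, k_mem: float, lam: float,
                 geometry: ProbeGeometry | None = None,
                 t: float = 300.0) -> float:
    """Solve the implicit forward problem for the flux q (m^3/s).

    The radial Darcy law q = 2 pi L K_total(r3) Delta_pi / ln(r3/r1) is
    coupled to the perfused-volume balance r3 = sqrt(q t/(pi L) + r2^2);
    the unique positive root is found by Brent's method on
    f(q) = q - q_darcy(q), which is negative at q = 0 and positive at the
    membrane-only flux (adding the tissue annulus can only reduce flow).
    """
    if delta_pi < 0:
        raise InvalidInputError("forward flux requires delta_pi >= 0")
    if delta_pi == 0.0:
        return 0.0
    geometry = geometry or ProbeGeometry()
    k_tis = tissue_permeability(lam)
    r1 = geometry.inner_membrane_radius
    r2 = geometry.outer_membrane_radius
    two_pi_l = 2.0 * math.pi * geometry.membrane_length

    def residual(q: float) -> float:
        r3 = perfusion_radius(q, t, geometry)
        if r3 <= r2:
            k_tot, logr = k_mem, geometry.membrane_log_ratio
        else:
            k_tot = effective_total_permeability(k_mem, k_tis, r1, r2, r3)
            logr = math.log(r3 / r1)
        return q - two_pi_l * k_tot * delta_pi / logr

    q_hi = membrane_flux(k_mem, geometry, delta_pi) * (1.0 + 1e-9)
    lo, hi = 0.0, q_hi
    if residual(hi) < 0:
        raise SolverError(
            f"no bracket for forward flux (delta_pi={delta_pi}, "
            f"k_mem={k_mem}, lambda={lam}): residual at membrane-only flux "
            f"{residual(hi):.3g}")
    return float(brentq(residual, lo, hi, xtol=1e-300, rtol=1e-14))


@dataclass
class SimulatedCohort:
    """Simulator output: the three input tables the pipeline consumes plus
    the generating ground truth and run metadata."""

    calibration: pd.DataFrame
    flux: pd.DataFrame
    icp: pd.DataFrame
    ground_truth: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write calibration.csv, flux.csv, icp.csv, ground_truth.csv and
        metadata.json under ``out_dir``; reruns are byte-identical."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("calibration", self.calibration),
                         ("flux", self.flux), ("icp", self.icp),
                         ("ground_truth", self.ground_truth)):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        meta_path = out / "metadata.json"
        meta_path.write_text(json.dumps(self.metadata, indent=2,
                                        sort_keys=True) + "\n")
        paths["metadata"] = meta_path
        return paths


def _sodium_from_osmolality(osm: float, constants: PhysicalConstants
                            ) -> float:
    """Invert total ions = c_na + c_ext^2/c_na for the generating
    intra-tissue sodium (mol/L) at osmolality ``osm`` (mOsm/kg)."""
    total = osm / (1000.0 * constants.osmotic_coefficient)  # mol/L
    c_ext = constants.bath_concentration
    disc = total * total - 4.0 * c_ext * c_ext
    if disc < 0:
        raise ConfigurationError(
            f"osmolality {osm} below the bath's: no Donnan-consistent sodium")
    return 0.5 * (total + math.sqrt(disc))


def simulate_cohort(config: SimulationConfig | None = None,
                    constants: PhysicalConstants | None = None,
                    geometry: ProbeGeometry | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    One probe per pressure group, calibrated at that pressure; per-sample
    ground-truth swelling pressure equal to the applied pressure; hydration
    declining linearly with pressure through the design anchors; lognormal
    measurement noise on fluxes, sodium and masses.
    """
    config = config or SimulationConfig()
    constants = constants or PhysicalConstants()
    geometry = geometry or ProbeGeometry()
    rng = np.random.default_rng(config.seed)
    area = geometry.tubing_cross_section
    t_total = config.perfusion_time
    frames = np.linspace(0.0, t_total, config.n_frames)

    def noisy(value: float, rel_sd: float, n: int = 1) -> np.ndarray:
        if rel_sd == 0:
            return np.full(n, value)
        sigma = math.sqrt(math.log1p(rel_sd * rel_sd))
        return value * rng.lognormal(-0.5 * sigma * sigma, sigma, n)

    cal_rows, flux_rows, icp_rows, truth_rows = [], [], [], []
    for gi, pressure in enumerate(config.applied_pressures):
        k_mem = config.membrane_permeability(pressure)

        # --- tissue samples equilibrated at this pressure; each sample
        # gets its own probe, calibrated at this pressure (membrane
        # permeability varies probe to probe in practice, so calibration
        # errors are independent across samples) ---
        hyd = _interp_line(pressure, _HYDRATION_ANCHORS)
        lam = ((1.0 + hyd) / (1.0 + EXCISION_HYDRATION)) ** (1.0 / 3.0)
        osm_truth = (constants.bath_osmotic_pressure + pressure) / constants.rt
        c_na_truth = _sodium_from_osmolality(osm_truth, constants)
        for si in range(config.samples_per_group):
            sample_id = f"s{gi + 1}{si + 1:02d}"
            probe_id = f"P{gi + 1}_{si + 1:02d}"

            # probe calibration in the PEG bath (membrane only)
            q_cal = membrane_flux(k_mem, geometry, pressure)
            q_obs = float(noisy(q_cal, config.flux_rel_sd)[0])
            for ti, pos in zip(frames, q_obs / area * frames):
                cal_rows.append({
                    "probe_id": probe_id,
                    "applied_pressure_Pa": pressure,
                    "peg_conc_g_per_mL": config.peg_concentrations[gi],
                    "t_s": ti,
                    "position_m": pos,
                })
            m0 = float(noisy(config.mean_excision_mass,
                             config.excision_mass_rel_sd)[0])
            dry = m0 / (1.0 + EXCISION_HYDRATION)
            mf = dry * (1.0 + hyd)  # == m0 * lam**3

            q_true = forward_flux(pressure, k_mem, lam, geometry, t_total)
            q_trip = noisy(q_true, config.flux_rel_sd, 3)
            post_flux = mf + 1000.0 * float(q_trip.mean()) * t_total

            m0_obs, mf_obs, post_obs, dry_obs = (
                float(noisy(m, config.mass_rel_sd)[0])
                for m in (m0, mf, post_flux, dry))
            flux_rows.append({
                "sample_id": sample_id, "probe_id": probe_id,
                "applied_pressure_Pa": pressure,
                "m0_kg": m0_obs, "mf_kg": mf_obs,
                "post_flux_wet_kg": post_obs, "dry_kg": dry_obs,
                "q1_m3s": q_trip[0], "q2_m3s": q_trip[1],
                "q3_m3s": q_trip[2], "t_s": t_total,
            })

            ttw_litres = post_flux - dry  # kg water == L
            na_total = float(noisy(c_na_truth, config.sodium_rel_sd)[0]) \
                * ttw_litres
            aliquot = min(5e-6, dry)
            icp_rows.append({
                "sample_id": sample_id,
                "na_mol": na_total * aliquot / dry,
                "wet_kg": post_obs, "dry_kg": dry_obs,
                "aliquot_dry_kg": aliquot,
            })
            truth_rows.append({
                "sample_id": sample_id,
                "applied_pressure_Pa": pressure,
                "delta_pi_Pa": pressure,
                "osmolality_mOsm": osm_truth,
                "c_na_molL": c_na_truth,
                "fcd_molL": c_na_truth
                - constants.bath_concentration ** 2 / c_na_truth,
                "hydration": hyd, "stretch_ratio": lam,
                "k_mem": k_mem, "q_true_m3s": q_true,
            })

    columns = {
        "calibration": ["probe_id", "applied_pressure_Pa",
                        "peg_conc_g_per_mL", "t_s", "position_m"],
        "flux": ["sample_id", "probe_id", "applied_pressure_Pa", "m0_kg",
                 "mf_kg", "post_flux_wet_kg", "dry_kg", "q1_m3s", "q2_m3s",
                 "q3_m3s", "t_s"],
        "icp": ["sample_id", "na_mol", "wet_kg", "dry_kg",
                "aliquot_dry_kg"],
        "ground_truth": ["sample_id", "applied_pressure_Pa", "delta_pi_Pa",
                         "osmolality_mOsm", "c_na_molL", "fcd_molL",
                         "hydration", "stretch_ratio", "k_mem",
                         "q_true_m3s"],
    }
    frames_out = {
        name: pd.DataFrame(rows, columns=columns[name])
        for name, rows in (("calibration", cal_rows), ("flux", flux_rows),
                           ("icp", icp_rows), ("ground_truth", truth_rows))
    }
    metadata = {"seed": config.seed, "config_hash": config.digest(),
                "n_groups": len(config.applied_pressures),
                "samples_per_group": config.samples_per_group}
    return SimulatedCohort(metadata=metadata, **frames_out)
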