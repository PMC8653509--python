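"""CSV schemas, YAML configuration, and metadata sidecars.

All files are comma-separated UTF-8 with '.' decimals; scientific notation
is accepted on read.  Headers are matched case-insensitively.  Row-level
problems are collected (with line numbers) rather than aborting the whole
file; a missing column is a schema error.

Every output CSV gets a JSON sidecar recording the package version, the
configuration hash and the physical constants used, so phi, T and c_ext
are always auditable.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .constants import PhysicalConstants
from .darcy_inference import SwellingResult, TissueFluxRecord
from .errors import ConfigurationError, OsmofluxError, SchemaError
from .gibbs_donnan import DonnanState, IcpOesRecord
from .instrument_model import (CalibrationRecord, DisplacementSeries,
                               ProbeGeometry, VirialCoefficients)

log = logging.getLogger("osmoflux")

__all__ = ["RunConfig", "load_config", "read_calibration_csv",
           "read_flux_csv", "read_icp_csv", "swelling_results_to_frame",
           "donnan_states_to_frame", "write_csv_with_metadata"]


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (constants + geometry + calibration
    conventions).  Invalid overrides fail at load time through the
    invariant checks of the underlying types."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    virial_coefficients: VirialCoefficients | None = None
    slope_method: str = "ols"
    hydrostatic_offset: float = 0.0
    seed: int = 0

    def digest(self) -> str:
        payload = {
            "constants": dataclasses.asdict(self.constants),
            "geometry": dataclasses.asdict(self.geometry),
            "virial": (None if self.virial_coefficients is None
                       else list(self.virial_coefficients.coefficients)),
            "slope_method": self.slope_method,
            "hydrostatic_offset": self.hydrostatic_offset,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    known = {"constants", "geometry", "virial_coefficients", "slope_method",
             "hydrostatic_offset", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    constants = PhysicalConstants(**raw.get("constants", {}))
    geometry = ProbeGeometry(**raw.get("geometry", {}))
    virial = raw.get("virial_coefficients")
    return RunConfig(
        constants=constants, geometry=geometry,
        virial_coefficients=(None if virial is None
                             else VirialCoefficients(virial)),
        slope_method=raw.get("slope_method", "ols"),
        hydrostatic_offset=float(raw.get("hydrostatic_offset", 0.0)),
        seed=int(raw.get("seed", 0)),
    )


def _read_table(path: str | Path, required: list[str],
                optional: list[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c.lower() not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _collect_rows(df: pd.DataFrame, builder, label: str):
    """Apply ``builder`` per row, collecting (line, message) failures.
    Line numbers are 1-based file lines (header is line 1)."""
    records, errors = [], []
    for idx, row in df.iterrows():
        try:
            rec = builder(row)
        except (OsmofluxError, ValueError, TypeError) as exc:
            errors.append((idx + 2, str(exc)))
            continue
        records.append(rec)
    for line, msg in errors:
        log.warning("%s row error (line %d): %s", label, line, msg)
    return records, errors


def read_calibration_csv(path: str | Path):
    """Read a long-format calibration CSV (one row per meniscus frame) into
    CalibrationRecords grouped by (probe, pressure/concentration).

    Returns (records, row_errors).
    """
    df = _read_table(path, ["probe_id", "t_s", "position_m"])
    has_p = "applied_pressure_pa" in df.columns
    has_c = "peg_conc_g_per_ml" in df.columns
    if not has_p and not has_c:
        raise SchemaError(f"{path}: need applied_pressure_Pa and/or "
                          "peg_conc_g_per_mL")
    keys = ["probe_id"] + (["applied_pressure_pa"] if has_p else []) \
        + (["peg_conc_g_per_ml"] if has_c else [])
    records, errors = [], []
    for key, grp in df.groupby(keys, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(keys, key))
        try:
            series = DisplacementSeries(
                grp["t_s"].astype(float).to_list(),
                grp["position_m"].astype(float).to_list())
            records.append(CalibrationRecord(
                probe_id=str(info["probe_id"]), series=series,
                peg_mass_concentration=(
                    float(info["peg_conc_g_per_ml"])
                    if has_c and pd.notna(info.get("peg_conc_g_per_ml"))
                    else None),
                applied_osmotic_pressure=(
                    float(info["applied_pressure_pa"])
                    if has_p and pd.notna(info.get("applied_pressure_pa"))
                    else None)))
        except (OsmofluxError, ValueError) as exc:
            errors.append((int(grp.index[0]) + 2, str(exc)))
            log.warning("calibration group %s error: %s", info, exc)
    return records, errors


def read_flux_csv(path: str | Path):
    """Read tissue flux records; returns (records, row_errors)."""
    df = _read_table(path, ["sample_id", "probe_id", "applied_pressure_pa",
                            "m0_kg", "mf_kg", "post_flux_wet_kg", "dry_kg",
                            "q1_m3s"])

    def build(row) -> TissueFluxRecord:
        fluxes = [float(row[c]) for c in ("q1_m3s", "q2_m3s", "q3_m3s")
                  if c in row.index and pd.notna(row[c])]
        return TissueFluxRecord(
            sample_id=str(row["sample_id"]), probe_id=str(row["probe_id"]),
            applied_pressure=float(row["applied_pressure_pa"]),
            excision_wet_mass=float(row["m0_kg"]),
            post_equilibration_wet_mass=float(row["mf_kg"]),
            post_flux_wet_mass=float(row["post_flux_wet_kg"]),
            dry_mass=float(row["dry_kg"]),
            triplicate_fluxes=tuple(fluxes),
            perfusion_time=float(row.get("t_s", 300.0)))

    return _collect_rows(df, build, "flux")


def read_icp_csv(path: str | Path):
    """Read ICP-OES sodium records; returns (records, row_errors)."""
    df = _read_table(path, ["sample_id", "na_mol", "wet_kg", "dry_kg"])

    def build(row) -> IcpOesRecord:
        aliquot = row.get("aliquot_dry_kg")
        return IcpOesRecord(
            sample_id=str(row["sample_id"]),
            sodium_mass=float(row["na_mol"]),
            sample_wet_mass=float(row["wet_kg"]),
            sample_dry_mass=float(row["dry_kg"]),
            aliquot_dry_mass=float(aliquot) if pd.notna(aliquot) else None)

    return _collect_rows(df, build, "icp")


def swelling_results_to_frame(results: list[SwellingResult]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in results]
    return pd.DataFrame(rows, columns=[
        "sample_id", "applied_pressure", "mean_flux", "perfusion_radius",
        "stretch_ratio", "k_tissue", "k_membrane", "k_total", "delta_pi",
        "pi_tissue_absolute", "osmolality", "hydration",
        "perfused_water_fraction"])


def donnan_states_to_frame(states: list[DonnanState]) -> pd.DataFrame:
    rows = [dataclasses.asdict(s) for s in states]
    return pd.DataFrame(rows, columns=[
        "sample_id", "c_na_int", "c_cl_int", "fcd", "total_ions",
        "ionic_swelling_pressure", "osmolality", "hydration",
        "donnan_consistent"])


def write_csv_with_metadata(df: pd.DataFrame, path: str | Path,
                            config: RunConfig, extra: dict | None = None
                            ) -> Path:
    """Write ``df`` and a JSON sidecar with version, config hash, and the
    physical constants actually used.  No timestamps, so identical inputs
    rerun byte-identically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {
        "package": "osmoflux",
        "version": __version__,
        "config_hash": config.digest(),
        "constants": dataclasses.asdict(config.constants),
        "geometry": dataclasses.asdict(config.geometry),
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path
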