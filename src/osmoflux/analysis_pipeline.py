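"""Statistical layer: group summaries, regressions, concordance, the
diurnal extrapolation, and the Donnan-vs-flux comparison.

Ordinary regression and rank correlation are delegated to statsmodels and
scipy; Lin's concordance correlation coefficient is implemented directly
from its definition (population moments), since the agreement statistic is
central to validating the method.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .constants import PhysicalConstants
from .errors import InvalidInputError
from .gibbs_donnan import donnan_fraction

__all__ = ["GroupSummary", "FitResult", "summarize_groups", "ols_fit",
           "diurnal_extrapolation", "lins_concordance", "spearman_rho",
           "donnan_vs_flux_report"]

#: Columns summarized per applied-pressure group.
SUMMARY_FIELDS = ("hydration", "c_na_int", "total_ions", "fcd",
                  "osm_icp", "osm_flux", "delta_osm")


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD of every measured quantity for one pressure group."""

    applied_pressure: float
    n: int
    means: dict
    sds: dict
    single_sample: bool = False  # SD is 0 by convention when n == 1


@dataclass(frozen=True)
class FitResult:
    """A least-squares polynomial fit (linear or quadratic).

    coefficients are in ascending power order (intercept first);
    p_value is the two-sided t-test p of the first-order coefficient.
    """

    form: str
    coefficients: tuple[float, ...]
    r_squared: float
    p_value: float
    n: int

    def predict(self, x: float) -> float:
        return float(sum(c * x ** k for k, c in enumerate(self.coefficients)))


def summarize_groups(df: pd.DataFrame,
                     reference_pressure: float = 0.21e6,
                     pressure_col: str = "applied_pressure"
                     ) -> list[GroupSummary]:
    """Per-pressure-group means and SDs of the per-sample results.

    ``df`` holds one row per sample with any subset of SUMMARY_FIELDS.
    The delta-osmolality column is each sample's flux osmolality minus the
    reference group's (default 0.21 MPa) mean flux osmolality, averaged
    within group; it is NaN with a warning when the reference group is
    absent.
    """
    if pressure_col not in df.columns:
        raise InvalidInputError(f"missing column {pressure_col!r}")
    work = df.copy()
    ref_mask = np.isclose(work[pressure_col], reference_pressure,
                          rtol=1e-6, atol=1.0)
    if "osm_flux" in work.columns and ref_mask.any():
        ref_mean = work.loc[ref_mask, "osm_flux"].mean()
        work["delta_osm"] = work["osm_flux"] - ref_mean
    else:
        if "osm_flux" in work.columns:
            warnings.warn(
                f"no samples at the reference pressure "
                f"{reference_pressure:.3g} Pa; delta osmolality omitted",
                stacklevel=2)
        work["delta_osm"] = np.nan

    out = []
    for pressure, grp in work.groupby(pressure_col, sort=True):
        fields = [f for f in SUMMARY_FIELDS if f in grp.columns]
        n = len(grp)
        means = {f: float(grp[f].mean()) for f in fields}
        sds = {f: (float(grp[f].std(ddof=1)) if n > 1 else 0.0)
               for f in fields}
        out.append(GroupSummary(applied_pressure=float(pressure), n=n,
                                means=means, sds=sds,
                                single_sample=(n == 1)))
    return out


def ols_fit(x, y, form: str = "linear") -> FitResult:
    """Least-squares polynomial fit with R^2 and slope p-value.

    form='linear' needs n >= 3; form='quadratic' n >= 4 (at least one
    residual degree of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be matching 1-D arrays")
    degree = {"linear": 1, "quadratic": 2}.get(form)
    if degree is None:
        raise InvalidInputError(f"unknown fit form {form!r}")
    if len(x) < degree + 2:
        raise InvalidInputError(
            f"{form} fit needs at least {degree + 2} points, got {len(x)}")
    design = sm.add_constant(
        np.column_stack([x ** k for k in range(1, degree + 1)]),
        has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise InvalidInputError("rank-deficient design (constant x?)")
    if np.ptp(y) == 0:  # constant response: flat line explains nothing
        coefs = (float(y[0]),) + (0.0,) * degree
        return FitResult(form=form, coefficients=coefs, r_squared=0.0,
                         p_value=1.0, n=len(x))
    res = sm.OLS(y, design).fit()
    return FitResult(form=form,
                     coefficients=tuple(float(c) for c in res.params),
                     r_squared=float(res.rsquared),
                     p_value=float(res.pvalues[1]),
                     n=len(x))


def diurnal_extrapolation(fit: FitResult, p_low: float = 0.2e6,
                          p_high: float = 0.6e6
                          ) -> tuple[float, float, float]:
    """Evaluate a linear osmolality-vs-pressure fit at the bounds of a
    simulated diurnal loading cycle (default 0.2 and 0.6 MPa).

    Returns (osmolality at p_low, osmolality at p_high, magnitude).
    """
    if fit.form != "linear":
        raise TypeError("diurnal extrapolation requires a linear fit")
    lo, hi = fit.predict(p_low), fit.predict(p_high)
    return lo, hi, hi - lo


def lins_concordance(x, y) -> float:
    """Lin's concordance correlation coefficient,

        rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2)

    with population (1/n) moments.  Measures agreement with the identity
    line: 1 is perfect concordance, 0 no agreement, -1 perfect reversed
    concordance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InvalidInputError("need paired 1-D samples with n >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population moments
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise InvalidInputError(
            "concordance undefined: zero variance and equal means")
    cov = ((x - mx) * (y - my)).mean()
    return float(2.0 * cov / denom)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties); returns
    (rho, p_value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InvalidInputError("rank correlation undefined for a constant "
                                "vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def donnan_vs_flux_report(donnan_df: pd.DataFrame,
                          swelling_df: pd.DataFrame,
                          constants: PhysicalConstants | None = None
                          ) -> dict:
    """Compare ionic (Gibbs-Donnan) and flux-based swelling per sample.

    ``donnan_df`` needs columns sample_id, osmolality; ``swelling_df``
    sample_id, applied_pressure, osmolality.  Returns per-sample fractions,
    per-group mean fractions, and the Spearman trend of fraction vs applied
    pressure (the gap between the two measures narrows with load when the
    trend is positive).
    """
    constants = constants or PhysicalConstants()
    merged = donnan_df.merge(swelling_df, on="sample_id",
                             suffixes=("_ion", "_flux"), validate="1:1")
    if len(merged) != len(donnan_df) or len(merged) != len(swelling_df):
        raise InvalidInputError("sample IDs of the two tables do not match")
    merged["donnan_fraction"] = [
        donnan_fraction(r["osmolality_ion"], r["osmolality_flux"], constants)
        for _, r in merged.iterrows()]
    per_group = (merged.groupby("applied_pressure")["donnan_fraction"]
                 .agg(["mean", "std", "count"]).reset_index())
    fractions = merged["donnan_fraction"]
    if (merged["applied_pressure"].nunique() >= 3
            and fractions.nunique() > 1):
        rho, p = spearman_rho(merged["applied_pressure"], fractions)
    else:
        rho, p = float("nan"), float("nan")  # trend undefined
    return {"per_sample": merged, "per_group": per_group,
            "trend_rho": rho, "trend_p": p}
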