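"""Pool-level statistics of reflex-amplitude estimates.

Standardized linear regression of reflex amplitude on background
discharge rate, one-tailed Pearson correlations with discharge rate and
recruitment threshold, per-activation-level amplitude dispersion, unit
tracking across levels, and empirical cumulative distribution (ECDF)
comparisons across pool compositions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
from statsmodels.distributions.empirical_distribution import ECDF

__all__ = [
    "RegressionResult",
    "CorrelationResult",
    "zscore",
    "fit_regression",
    "pearson_one_tailed",
    "correlation_rating",
    "amplitude_cov",
    "amplitude_cov_per_level",
    "ecdf_compare",
    "ecdf_shift",
    "track_units",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope
    residuals: np.ndarray
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float  # one-tailed, in the expected direction
    n: int
    rating: str  # poor | fair | moderate | strong


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, population SD 1: z = (x - mean) / sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-score needs at least two values")
    sd = x.std()
    if sd == 0:
        raise ValueError("z-score undefined for a constant vector")
    return (x - x.mean()) / sd


def fit_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y ~ x with a two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs matched samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for degenerate x")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        residuals=np.asarray(model.resid),
        n=int(x.size),
    )


#: |rho| cut points of the conventional correlation-strength scale
_RATING_EDGES = ((0.8, "strong"), (0.5, "moderate"), (0.3, "fair"))


def correlation_rating(rho: float) -> str:
    a = abs(rho)
    for edge, name in _RATING_EDGES:
        if a >= edge:
            return name
    return "poor"


def pearson_one_tailed(
    x: np.ndarray, y: np.ndarray, expected_sign: str = "positive"
) -> CorrelationResult:
    """Pearson correlation with a one-tailed test in the expected direction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation needs matched samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    alternative = {"positive": "greater", "negative": "less"}[expected_sign]
    res = sstats.pearsonr(x, y, alternative=alternative)
    rho = float(res.statistic)
    return CorrelationResult(rho, float(res.pvalue), int(x.size), correlation_rating(rho))


def amplitude_cov(amplitudes: np.ndarray) -> float:
    """Coefficient of variation (%) of amplitudes, population SD."""
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        raise ValueError("CoV needs at least two amplitudes")
    mean = a.mean()
    if mean == 0:
        raise ValueError("CoV undefined for zero-mean amplitudes")
    return 100.0 * a.std() / mean


def amplitude_cov_per_level(
    results: pd.DataFrame,
    method: str = "psf",
    amplitude_col: str = "normalized_amplitude",
) -> pd.Series:
    """CoV (%) of normalized amplitudes among significant units, per level.

    ``results`` is the tidy per-unit results table with at least the columns
    ``level``, ``method``, ``significant`` and the amplitude column. Levels
    with fewer than two significant units are reported as NaN.
    """
    sel = results[(results["method"] == method) & results["significant"]]

    def _cov(group: pd.Series) -> float:
        return amplitude_cov(group.to_numpy()) if group.size >= 2 else float("nan")

    return sel.groupby("level")[amplitude_col].apply(_cov)


def ecdf_compare(
    samples: dict[str, np.ndarray],
) -> dict[str, ECDF]:
    """ECDF per labelled sample (e.g. one pool composition each).

    Returns callable step functions; stochastic ordering between two pools
    can be read off by evaluating both on a common grid.
    """
    out: dict[str, ECDF] = {}
    for label, values in samples.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"empty sample for {label!r}")
        out[label] = ECDF(values)
    return out


def ecdf_shift(a: np.ndarray, b: np.ndarray) -> float:
    """Signed mean ECDF gap between samples: positive when ``a`` is shifted
    toward larger values than ``b`` (i.e. ECDF_a lies below ECDF_b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grid = np.union1d(a, b)
    return float(np.mean(ECDF(b)(grid) - ECDF(a)(grid)))


def track_units(
    results: pd.DataFrame,
    method: str = "psf",
    amplitude_col: str = "normalized_amplitude",
    significant_only: bool = True,
) -> pd.DataFrame:
    """Per-unit amplitude trajectories across activation levels.

    Returns a (unit x level) table of amplitudes with two summary columns:
    ``monotone_decreasing`` (amplitude never increases across the levels at
    which the unit has an estimate) and ``u_shaped`` (a strict decrease
    followed by a strict increase).
    """
    sel = results[results["method"] == method]
    if significant_only:
        sel = sel[sel["significant"]]
    table = sel.pivot_table(index="unit", columns="level", values=amplitude_col)

    def _flags(row: pd.Series) -> pd.Series:
        vals = row.dropna().to_numpy()
        if vals.size < 2:
            return pd.Series({"monotone_decreasing": False, "u_shaped": False})
        d = np.diff(vals)
        mono = bool(np.all(d <= 0))
        argmin = int(np.argmin(vals))
        u = bool(
            0 < argmin < vals.size - 1
            and vals[0] > vals[argmin]
            and vals[-1] > vals[argmin]
        )
        return pd.Series({"monotone_decreasing": mono, "u_shaped": u})

    flags = table.apply(_flags, axis=1)
    return table.join(flags)
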