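"""Method-comparison statistics.

Zero-order and partial Pearson correlation, Bland-Altman agreement with a
trend test, compliance accounting, and the one-sided high 3-SD outlier rule
used for sensitivity reanalysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _sps

from .constants import DEFAULTS, StudyConstants


class DegenerateInputError(ValueError):
    """Zero variance or rank-deficient inputs make the statistic undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    kind: str  # "zero_order" | "partial"
    df: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary for paired measurements a (test) vs b (reference).

    Differences are a - b; limits of agreement are mean_diff +/- 1.96 SD.
    The trend block is the OLS regression of difference on pair mean.
    """

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    trend_slope: float
    trend_intercept: float
    trend_r: float
    trend_p: float
    n: int


def _as_finite_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _r_to_p(r: float, df: int) -> float:
    """Two-sided p for a correlation via t = r sqrt(df / (1 - r^2))."""
    if df <= 0:
        return float("nan")
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt(df / (1.0 - r2))
    return float(2.0 * _sps.t.sf(t, df))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with its two-sided p-value (df = n - 2)."""
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("zero variance in x or y")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(r=r, p=_r_to_p(r, n - 2), n=n,
                             kind="zero_order", df=n - 2)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """OLS residuals of v on [1, z]; raises on rank deficiency."""
    design = np.column_stack([np.ones(v.size), z])
    coef, _, rank, _ = np.linalg.lstsq(design, v, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateInputError("collinear covariates (rank-deficient design)")
    return v - design @ coef


def partial_pearson(x: Sequence[float], y: Sequence[float],
                    covariates) -> CorrelationResult:
    """Partial correlation of x and y controlling for covariates.

    Computed as the correlation of the OLS residuals of x and y regressed on
    the covariates (with intercept); p uses df = n - 2 - k. With an empty
    covariate set this reduces to :func:`pearson`.
    """
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    z = np.asarray(covariates, dtype=float)
    if z.size == 0:
        return pearson(xa, ya)
    if z.ndim == 1:
        z = z[:, None]
    if not np.all(np.isfinite(z)):
        raise ValueError("covariates contain non-finite values")
    n, k = z.shape
    if xa.size != n or ya.size != n:
        raise ValueError("x, y and covariates must have equal length")
    if n <= k + 2:
        raise ValueError(f"need n > covariates + 2, got n={n}, k={k}")
    rx = _residualize(xa, z)
    ry = _residualize(ya, z)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateInputError(
            "residual variance collapsed: variable explained by covariates"
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(r=r, p=_r_to_p(r, n - 2 - k), n=n,
                             kind="partial", df=n - 2 - k)


def loa_from_summary(mean_diff: float, half_width: float) -> Tuple[float, float]:
    """Reconstruct limits of agreement from a printed mean difference and
    +/- 1.96 SD half-width: (mean - half_width, mean + half_width)."""
    if half_width < 0:
        raise ValueError("half-width must be non-negative")
    return mean_diff - half_width, mean_diff + half_width


def bland_altman(a: Sequence[float], b: Sequence[float],
                 constants: StudyConstants = DEFAULTS) -> BlandAltmanResult:
    """Bland-Altman agreement of method a against method b (same units).

    Differences a - b on the y axis against pair means (a + b)/2 on the x
    axis; limits of agreement are mean_diff +/- 1.96 x sample SD (ddof=1);
    the trend test is the OLS slope of difference on mean (its p equals the
    correlation p for that regression).
    """
    aa = _as_finite_1d(a, "a")
    bb = _as_finite_1d(b, "b")
    if aa.size != bb.size:
        raise ValueError("a and b must have equal length")
    n = aa.size
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    diff = aa - bb
    mean = (aa + bb) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    half = constants.loa_multiplier * sd_diff
    if np.ptp(mean) == 0 or sd_diff == 0:
        slope = intercept = trend_r = 0.0
        trend_p = 1.0
    else:
        fit = _sps.linregress(mean, diff)
        slope, intercept = float(fit.slope), float(fit.intercept)
        trend_r, trend_p = float(fit.rvalue), float(fit.pvalue)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - half,
        loa_high=mean_diff + half,
        trend_slope=slope,
        trend_intercept=intercept,
        trend_r=trend_r,
        trend_p=trend_p,
        n=n,
    )


def compliance(completed: int, total: int) -> Tuple[int, int, float]:
    """Completion accounting: (completed, total, percent to 1 decimal)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= completed <= total):
        raise ValueError("completed must be in [0, total]")
    return completed, total, round(100.0 * completed / total, 1)


def flag_outliers(values: Sequence[float], k_sd: float = 3.0) -> list:
    """Indices of values more than ``k_sd`` SDs above the mean.

    One-sided high, matching the sensitivity-reanalysis rule for a gross
    overestimator; rerunning the statistics on the retained set is the
    caller's second pass.
    """
    arr = _as_finite_1d(values, "values")
    if arr.size < 3:
        raise ValueError("need n >= 3 values")
    sd = arr.std(ddof=1)
    if sd == 0 or not math.isfinite(k_sd):
        return []
    cut = arr.mean() + k_sd * sd
    return [int(i) for i in np.nonzero(arr > cut)[0]]


def paired_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Paired t-test of method means; returns (t, two-sided p)."""
    aa = _as_finite_1d(a, "a")
    bb = _as_finite_1d(b, "b")
    res = _sps.ttest_rel(aa, bb)
    return float(res.statistic), float(res.pvalue)
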