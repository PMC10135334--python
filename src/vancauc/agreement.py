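"""Method-comparison statistics: Bland-Altman, Pearson, Lin's CCC, OLS.

Differences are estimate minus reference, so a positive bias means the
two-point equation overestimates the reference AUC.  The percent bias is
normalized by the grand mean of both methods (the mean of all 2n values),
which keeps adult (hundreds of mg*h/L) and pediatric (around a hundred)
cohorts on one percentage scale.  Limits of agreement use the conventional
mean +/- 1.96 SD of the differences.

Lin's concordance correlation coefficient uses the original 1/n-moment
definition

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

with inference via the z-transform and Lin's asymptotic variance; it
penalizes location and scale shifts that Pearson's r ignores, so
|rho_c| <= |r| always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementSummary",
    "bland_altman",
    "pearson",
    "lin_ccc",
    "ols_fit",
    "summarize",
]


@dataclass(frozen=True)
class AgreementSummary:
    """All agreement statistics for one estimator-vs-reference comparison."""

    n: int
    grand_mean: float
    mean_diff: float
    pct_mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    pearson_p: float
    lin_ccc: float
    lin_p: float
    ols_slope: float
    ols_intercept: float
    ols_r2: float


def _paired(ref, est) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(ref, dtype=float)
    y = np.asarray(est, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ref and est must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("AUC values must be positive")
    return x, y


def bland_altman(ref, est) -> dict:
    """Bias and 95% limits of agreement of est - ref.

    Returns grand_mean (mean of all values of both methods), mean_diff,
    pct_mean_diff = 100*mean_diff/grand_mean, sd_diff (ddof=1) and
    loa_low/high = mean_diff -/+ 1.96 sd_diff.
    """
    x, y = _paired(ref, est)
    d = y - x
    grand = float(np.concatenate([x, y]).mean())
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "grand_mean": grand,
        "mean_diff": md,
        "pct_mean_diff": 100.0 * md / grand,
        "sd_diff": sd,
        "loa_low": md - 1.96 * sd,
        "loa_high": md + 1.96 * sd,
    }


def pearson(ref, est) -> tuple[float, float]:
    """Product-moment correlation with two-sided p-value."""
    x, y = _paired(ref, est)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def lin_ccc(ref, est) -> tuple[float, float]:
    """Lin's concordance correlation (1/n moments) with z-transform p-value."""
    x, y = _paired(ref, est)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sx2 = float(((x - mx) ** 2).mean())
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("zero variance in both series: CCC undefined")
    ccc = 2.0 * sxy / denom
    # inference: Lin (1989) asymptotic variance of atanh(ccc)
    if sx2 == 0 or sy2 == 0 or abs(ccc) >= 1:
        return ccc, 0.0 if abs(ccc) >= 1 else 1.0
    r = sxy / math.sqrt(sx2 * sy2)
    if r == 0:
        return ccc, 1.0
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2, r2 = ccc * ccc, r * r
    var_z = (
        (1 - r2) * c2 / ((1 - c2) * r2)
        + 4 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - 2 * ccc**4 * u**4 / (r2 * (1 - c2) ** 2)
    ) / (n - 2)
    if var_z <= 0:
        return ccc, 0.0
    z = math.atanh(ccc)
    p = 2.0 * stats.norm.sf(abs(z) / math.sqrt(var_z))
    return ccc, float(p)


def ols_fit(ref, est) -> tuple[float, float, float]:
    """Ordinary least squares of est on ref: (slope, intercept, r^2)."""
    x, y = _paired(ref, est)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in reference: OLS undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def summarize(ref, est) -> AgreementSummary:
    """Compute the full agreement panel for one paired series."""
    x, y = _paired(ref, est)
    ba = bland_altman(x, y)
    r, rp = pearson(x, y)
    ccc, cp = lin_ccc(x, y)
    slope, intercept, r2 = ols_fit(x, y)
    return AgreementSummary(
        n=len(x),
        pearson_r=r,
        pearson_p=rp,
        lin_ccc=ccc,
        lin_p=cp,
        ols_slope=slope,
        ols_intercept=intercept,
        ols_r2=r2,
        **ba,
    )
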