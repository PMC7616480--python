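"""Method-agreement statistics for validating body-composition predictions.

The battery applied to every predicted-vs-reference comparison:

* MAPE, mean absolute percentage error;
* Pearson's r and Lin's concordance correlation coefficient (CCC), which
  penalises location and scale shifts as well as scatter, with a Fisher-z
  asymptotic confidence interval;
* Bland-Altman bias, SD of differences and 95% limits of agreement
  (bias +/- 1.96 SD), plus a proportional-bias test (t-test on the OLS slope
  of the differences against the pairwise means);
* Passing-Bablok regression: the nonparametric shifted-median-of-pairwise-
  slopes estimator with rank-based confidence intervals;
* TOST equivalence: two one-sided paired t-tests against +/- bound; the
  equivalence decision is identical to the 90% CI of the mean difference
  lying strictly inside the bounds.

Differences are ``predicted - reference`` throughout, so a positive bias
means the candidate method overestimates the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "mape",
    "ccc",
    "bland_altman",
    "passing_bablok",
    "tost",
    "percent_of_mean",
    "evaluate_agreement",
]


def _paired(predicted, reference, min_n: int = 3):
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("predicted and reference must be 1-d arrays of equal length")
    if p.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {p.size}")
    return p, r


def mape(predicted, reference) -> float:
    """Mean absolute percentage error, 100/n * sum|pred - ref|/ref."""
    p, r = _paired(predicted, reference, min_n=1)
    if np.any(r <= 0):
        raise ValueError("all reference values must be positive for MAPE")
    return float(100.0 * np.mean(np.abs(p - r) / r))


def ccc(predicted, reference, alpha: float = 0.05) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    Uses n-denominator moments (Lin's original definition) and the standard
    asymptotic variance of the z-transformed estimate.
    """
    p, r = _paired(predicted, reference)
    n = p.size
    mp_, mr = p.mean(), r.mean()
    sp2 = float(np.mean((p - mp_) ** 2))
    sr2 = float(np.mean((r - mr) ** 2))
    spr = float(np.mean((p - mp_) * (r - mr)))
    if sp2 == 0 or sr2 == 0:
        raise ValueError("CCC undefined for zero-variance input")
    rho_c = 2.0 * spr / (sp2 + sr2 + (mp_ - mr) ** 2)
    pearson = spr / np.sqrt(sp2 * sr2)
    if abs(rho_c) >= 1.0 or pearson == 0:
        return float(rho_c), float(rho_c), float(rho_c)
    # Lin's asymptotic variance of atanh(ccc)
    u = (mp_ - mr) / (sp2 * sr2) ** 0.25
    r2 = pearson**2
    c2 = rho_c**2
    var_z = (
        (1 - r2) * c2 / ((1 - c2) ** 2 * r2)
        + 2 * rho_c**3 * (1 - rho_c) * u**2 / (pearson * (1 - c2) ** 2)
        - rho_c**4 * u**4 / (2 * r2 * (1 - c2) ** 2)
    ) / (n - 2)
    z = np.arctanh(rho_c)
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var_z, 0.0))
    return float(rho_c), float(np.tanh(z - half)), float(np.tanh(z + half))


@dataclass
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    proportional_bias_p: float


def bland_altman(predicted, reference) -> BlandAltman:
    """Bias, SD of differences (n-1), 95% LOA and the proportional-bias p.

    The proportional-bias p-value is the two-sided t-test on the OLS slope of
    the differences regressed on the pairwise means (predicted+reference)/2.
    """
    p, r = _paired(predicted, reference)
    d = p - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mean_pair = (p + r) / 2.0
    if np.ptp(mean_pair) == 0 or sd == 0:
        prop_p = float("nan") if np.ptp(mean_pair) == 0 else 1.0
        if sd == 0:
            prop_p = 1.0
    else:
        prop_p = float(stats.linregress(mean_pair, d).pvalue)
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        proportional_bias_p=prop_p,
    )


@dataclass
class PassingBablok:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]


def passing_bablok(predicted, reference, alpha: float = 0.05) -> PassingBablok:
    """Passing-Bablok regression of predicted (y) on reference (x).

    All pairwise slopes are enumerated; slopes with zero denominator are
    undefined and dropped, slopes equal to -1 are excluded, and the slope is
    the median shifted by K, the number of slopes below -1 (the original
    offset correction for negative correlation invariance).  Confidence
    intervals are the standard rank-based ones; the intercept is
    median(y - slope*x) with its CI from the slope CI endpoints.
    """
    y, x = _paired(predicted, reference)
    if np.ptp(x) == 0:
        raise ValueError("all reference values identical; slope undefined")
    n = x.size
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    mask = dx != 0
    s = dy[mask] / dx[mask]
    s = np.sort(s[s != -1.0])
    ns = s.size
    if ns == 0:
        raise ValueError("no valid pairwise slopes")
    k_off = int(np.sum(s < -1.0))

    def shifted_median(arr, offset):
        m = arr.size
        if m % 2 == 1:
            return float(arr[np.clip((m - 1) // 2 + offset, 0, m - 1)])
        lo = np.clip(m // 2 - 1 + offset, 0, m - 1)
        hi = np.clip(m // 2 + offset, 0, m - 1)
        return float(0.5 * (arr[lo] + arr[hi]))

    slope = shifted_median(s, k_off)
    w = stats.norm.ppf(1 - alpha / 2) * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((ns - w) / 2.0))
    m2 = ns - m1 + 1
    lo_i = np.clip(m1 - 1 + k_off, 0, ns - 1)
    hi_i = np.clip(m2 - 1 + k_off, 0, ns - 1)
    slope_ci = (float(s[lo_i]), float(s[hi_i]))
    intercept = float(np.median(y - slope * x))
    intercept_ci = (
        float(np.median(y - slope_ci[1] * x)),
        float(np.median(y - slope_ci[0] * x)),
    )
    return PassingBablok(
        slope=slope, intercept=intercept, slope_ci=slope_ci, intercept_ci=intercept_ci
    )


def tost(
    predicted, reference, bound: float
) -> tuple[float, tuple[float, float], bool]:
    """Paired TOST equivalence test against symmetric bounds +/- ``bound``.

    Returns (p, 90% CI of the mean difference, equivalent flag).  p is the
    larger of the two one-sided p-values; the flag (p < 0.05) coincides
    exactly with the 90% CI lying inside (-bound, +bound).  Zero-variance
    differences are handled as exact: equivalent iff |mean| < bound.
    """
    if bound <= 0:
        raise ValueError("equivalence bound must be positive")
    p_arr, r_arr = _paired(predicted, reference)
    d = p_arr - r_arr
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        equivalent = abs(mean) < bound
        return (0.0 if equivalent else 1.0), (mean, mean), bool(equivalent)
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (mean + bound) / se  # H0: mean <= -bound
    t_upper = (mean - bound) / se  # H0: mean >= +bound
    p_lower = float(stats.t.sf(t_lower, df))
    p_upper = float(stats.t.cdf(t_upper, df))
    p_val = max(p_lower, p_upper)
    half = stats.t.ppf(0.95, df) * se
    ci90 = (mean - half, mean + half)
    return p_val, ci90, bool(p_val < 0.05)


def percent_of_mean(value_kg: float, mean_reference_kg: float) -> float:
    """Express an absolute quantity as a percentage of the reference mean."""
    if mean_reference_kg <= 0:
        raise ValueError("mean reference must be positive")
    return 100.0 * value_kg / mean_reference_kg


@dataclass
class AgreementReport:
    """Full validation battery for one method against the reference."""

    n: int
    bias_kg: float
    sd_diff_kg: float
    loa_low_kg: float
    loa_high_kg: float
    bias_pct_of_mean: float
    mape_pct: float
    pearson_r: float
    ccc: float
    ccc_ci: tuple[float, float]
    pb_slope: float
    pb_intercept: float
    pb_slope_ci: tuple[float, float]
    pb_intercept_ci: tuple[float, float]
    proportional_bias_p: float
    tost_bound_kg: float
    tost_ci90: tuple[float, float]
    tost_p: float
    equivalent: bool


def evaluate_agreement(
    predicted,
    reference,
    tost_bound: float = 0.25,
    mean_reference: Optional[float] = None,
) -> AgreementReport:
    """Assemble the full agreement battery for one method.

    ``mean_reference`` defaults to the sample mean of the reference values;
    pass a cohort-level mean to express biases on a common percentage scale.
    """
    p, r = _paired(predicted, reference)
    ba = bland_altman(p, r)
    ccc_val, ccc_lo, ccc_hi = ccc(p, r)
    pb = passing_bablok(p, r)
    tost_p, ci90, equiv = tost(p, r, tost_bound)
    mref = float(np.mean(r)) if mean_reference is None else float(mean_reference)
    return AgreementReport(
        n=int(p.size),
        bias_kg=ba.bias,
        sd_diff_kg=ba.sd,
        loa_low_kg=ba.loa_low,
        loa_high_kg=ba.loa_high,
        bias_pct_of_mean=percent_of_mean(ba.bias, mref),
        mape_pct=mape(p, r),
        pearson_r=float(stats.pearsonr(p, r).statistic),
        ccc=ccc_val,
        ccc_ci=(ccc_lo, ccc_hi),
        pb_slope=pb.slope,
        pb_intercept=pb.intercept,
        pb_slope_ci=pb.slope_ci,
        pb_intercept_ci=pb.intercept_ci,
        proportional_bias_p=ba.proportional_bias_p,
        tost_bound_kg=float(tost_bound),
        tost_ci90=ci90,
        tost_p=tost_p,
        equivalent=equiv,
    )
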