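"""Intraclass correlation for continuous measurements.

The reliability of the continuous third molar maturity index is estimated
with the two-way, absolute-agreement, single-measure ICC (ICC(A,1) in the
McGraw-Wong taxonomy; "two-way mixed, absolute agreement" shares the same
point estimate with the two-way random form — the mixed label changes only
the inference population).  Subjects are rows, raters (or sessions)
columns, of a complete two-way layout:

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C, MS_E are the subject, rater and residual mean squares of
the additive two-way ANOVA.  Absolute agreement charges systematic rater
offsets (through MS_C) against reliability, unlike the consistency form.
The 95% CI is the standard F-based interval for this form; the p-value
tests MS_R / MS_E against 1.

Rows with any missing cell are dropped (listwise deletion keeps the ANOVA
balanced); the number of observations actually used is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError
from .study import RatingMatrix


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    k_raters: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_observations: int
    n_dropped: int = 0
    degenerate: bool = False
    note: str = ""

    def benchmark(self, scale: str = "portney_watkins") -> str:
        from .agreement import benchmark_label

        return benchmark_label(self.icc, scale)


def icc_absolute(data, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) from an n x k array (or RatingMatrix) of continuous ratings."""
    if isinstance(data, RatingMatrix):
        x = data.float_values()
    else:
        x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x raters array")
    complete = ~np.isnan(x).any(axis=1)
    n_dropped = int((~complete).sum())
    x = x[complete]
    n, k = x.shape
    if k < 2:
        raise InsufficientDataError("need >= 2 raters")
    if n < 3:
        raise InsufficientDataError("need >= 3 complete subject rows")

    grand = x.mean()
    rowm = x.mean(axis=1)
    colm = x.mean(axis=0)
    ss_rows = k * ((rowm - grand) ** 2).sum()
    ss_cols = n * ((colm - grand) ** 2).sum()
    resid = x - rowm[:, None] - colm[None, :] + grand
    ss_err = (resid**2).sum()
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr == 0 and msc == 0 and mse == 0):
        return ICCResult(
            float("nan"), float("nan"), float("nan"), float("nan"),
            n, k, msr, msc, mse, n * k, n_dropped,
            degenerate=True, note="zero total variance",
        )
    icc = (msr - mse) / denom

    # F-based interval for ICC(A,1) (McGraw & Wong 1996)
    if mse > 0:
        fobs = msr / mse
        p = float(stats.f.sf(fobs, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0
    if 1.0 - icc < 1e-12:
        # exact agreement: the F interval degenerates to the point [1, 1]
        return ICCResult(1.0, 1.0, 1.0, p, n, k, float(msr), float(msc), float(mse),
                         n * k, n_dropped)
    one_m = 1.0 - icc
    a = k * icc / (n * one_m)
    b = 1.0 + k * icc * (n - 1) / (n * one_m)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else n - 1
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lo, hi = float(min(lo, icc)), float(min(max(hi, icc), 1.0))
    return ICCResult(float(icc), lo, hi, p, n, k, float(msr), float(msc), float(mse), n * k, n_dropped)


def icc_intra(pairs, alpha: float = 0.05) -> ICCResult:
    """Intra-observer ICC from (session-1, session-2) measurement pairs.

    NA-bearing pairs are dropped (listwise) and counted.
    """
    rows = []
    for a, b in pairs:
        av = np.nan if a is None else float(a)
        bv = np.nan if b is None else float(b)
        rows.append((av, bv))
    return icc_absolute(np.asarray(rows, dtype=float), alpha=alpha)
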