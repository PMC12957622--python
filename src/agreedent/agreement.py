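"""Chance-corrected agreement coefficients for ordinal rating matrices.

All coefficients share the form (p_a - p_e) / (1 - p_e), where p_a is the
observed (weighted pairwise) agreement and p_e the agreement expected by
chance; they differ only in the chance model:

* weighted Cohen's kappa (two raters): p_e from the product of the two
  raters' marginal distributions;
* Fleiss' kappa (many raters): p_e = sum_q pi_q^2, with pi_q the mean
  classification proportion of category q;
* Gwet's AC1/AC2 (many raters): p_e = (T_w / (Q(Q-1))) * sum_q pi_q(1-pi_q),
  the chance term of a rater who classifies at random only part of the
  time.  This keeps the coefficient stable when one category dominates —
  the "kappa paradox" situation in which kappa collapses toward 0 despite
  raw agreement above 90%.  AC2 is AC1 with non-identity weights; with
  identity weights T_w = Q and the two coincide.

Missing ratings (NA) are dropped cell-wise: a unit contributes to p_a
whenever at least two of its ratings remain, and to the category
prevalences pi_q whenever at least one remains.  Standard errors come from
the unit-level linearization of the estimator (variance of per-unit
contributions divided by the number of units); confidence intervals are
normal-theory, truncated to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError
from .study import RatingMatrix
from .weights import WeightMatrix, build_weights

Z975 = float(stats.norm.ppf(0.975))

LANDIS_KOCH_BINS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.01, "almost perfect"),
)


@dataclass(frozen=True)
class AgreementResult:
    """Coefficient estimate with uncertainty and bookkeeping counts."""

    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_units: int
    n_observations: int
    null_value: float
    method: str
    p_a: float = float("nan")
    p_e: float = float("nan")
    degenerate: bool = False
    note: str = ""

    def benchmark(self, scale: str = "landis_koch") -> str:
        return benchmark_label(self.coefficient, scale)


def benchmark_label(coefficient: float, scale: str = "landis_koch") -> str:
    """Conventional verbal label for a coefficient magnitude.

    ``landis_koch``: <0 poor, [0, 0.20] slight, (0.20, 0.40] fair,
    (0.40, 0.60] moderate, (0.60, 0.80] substantial, (0.80, 1] almost
    perfect.  ``portney_watkins`` (for ICC): <0.5 poor, [0.5, 0.75)
    moderate, [0.75, 0.9) good, >= 0.9 excellent.
    """
    if not np.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    if scale == "landis_koch":
        if coefficient < 0:
            return "poor"
        for upper, label in LANDIS_KOCH_BINS[1:]:
            if coefficient <= upper:
                return label
        return "almost perfect"
    if scale == "portney_watkins":
        if coefficient < 0.5:
            return "poor"
        if coefficient < 0.75:
            return "moderate"
        if coefficient < 0.9:
            return "good"
        return "excellent"
    raise ValueError(f"unknown benchmark scale {scale!r}")


def _ci_p(coef, se, null_value, sided):
    lo = max(-1.0, coef - Z975 * se)
    hi = min(1.0, coef + Z975 * se)
    if se > 0:
        z = (coef - null_value) / se
        p = float(stats.norm.sf(z)) if sided == "one" else float(2 * stats.norm.sf(abs(z)))
    else:
        if sided == "one":
            p = 0.0 if coef > null_value else 1.0
        else:
            p = 0.0 if coef != null_value else 1.0
    return lo, hi, min(p, 1.0)


def _pairwise_pa(r: np.ndarray, w: np.ndarray):
    """Per-unit weighted pairwise agreement from category counts r (n x Q).

    Returns (pa_per_unit, informative_mask); uninformative units (fewer
    than 2 ratings) get pa 0 and mask False.
    """
    ri = r.sum(axis=1)
    rw = r @ w
    num = (r * rw).sum(axis=1) - ri  # ordered agreeing pairs, weighted
    den = ri * (ri - 1)
    ok = den > 0
    pa = np.zeros(len(r))
    pa[ok] = num[ok] / den[ok]
    return pa, ok


def percent_agreement(matrix: RatingMatrix, weights: WeightMatrix | None = None) -> float:
    """Average over informative units of the weighted pairwise agreement.

    Identity weights give the plain proportion of matching rating pairs.
    """
    if weights is None:
        weights = build_weights(matrix.scheme.categories, "identity")
    r = matrix.counts(weights.categories)
    pa, ok = _pairwise_pa(r, weights.w)
    if not ok.any():
        raise InsufficientDataError("no unit has two or more non-NA ratings")
    return float(pa[ok].mean())


def gwet_ac(
    matrix: RatingMatrix,
    weights: WeightMatrix,
    null_value: float = 0.0,
    sided: str = "two",
) -> AgreementResult:
    """Gwet's AC1 (identity weights) / AC2 (weighted) with linearized SE.

    p_e = (T_w / (Q(Q-1))) * sum_q pi_q (1 - pi_q), with pi_q the mean over
    units of the within-unit proportion of ratings in category q.
    """
    r = matrix.counts(weights.categories)
    n_obs = int(r.sum())
    label = "gwet_ac1" if weights.is_identity else "gwet_ac2"
    q = weights.q
    ri = r.sum(axis=1)
    r = r[ri > 0]
    ri = ri[ri > 0]
    n = len(r)
    if q == 1:
        return AgreementResult(
            1.0, 0.0, 1.0, 1.0, float("nan"), n, n_obs, null_value, label,
            degenerate=True, note="single observed category: chance term undefined",
        )
    pa_i, ok = _pairwise_pa(r, weights.w)
    n2 = int(ok.sum())
    if n2 < 2:
        raise InsufficientDataError("need >= 2 units with >= 2 non-NA ratings")
    pa = float(pa_i[ok].mean())
    pi = (r / ri[:, None]).mean(axis=0)  # each unit weighted equally
    pe = float(weights.total / (q * (q - 1)) * (pi * (1 - pi)).sum())
    coef = (pa - pe) / (1 - pe)

    # unit-level linearization (jackknife-free influence form)
    ac_i = np.where(ok, (n / n2) * (pa_i - pe * ok) / (1 - pe), 0.0)
    pe_i = (weights.total / (q * (q - 1))) * (r @ (1 - pi)) / ri
    ac_star = ac_i - 2 * (1 - coef) * (pe_i - pe) / (1 - pe)
    var = float(((ac_star - coef) ** 2).sum() / (n * (n - 1))) if n > 1 else 0.0
    se = np.sqrt(max(var, 0.0))
    lo, hi, p = _ci_p(coef, se, null_value, sided)
    return AgreementResult(
        float(coef), float(se), lo, hi, p, n, n_obs, null_value, label, p_a=pa, p_e=pe
    )


def cohen_kappa_weighted(
    pairs,
    weights: WeightMatrix,
    null_value: float = 0.0,
    sided: str = "two",
) -> AgreementResult:
    """Weighted Cohen's kappa for one rater pair (e.g. two sessions).

    ``pairs`` is an iterable of (value_a, value_b); pairs with an NA on
    either side are excluded beforehand and only counted.  The SE is the
    large-sample weighted-kappa variance of Fleiss, Cohen & Everitt.
    """
    cats = weights.categories
    pos = {c: k for k, c in enumerate(cats)}
    q = weights.q
    f = np.zeros((q, q))
    n_na = 0
    for a, b in pairs:
        if a is None or b is None:
            n_na += 1
            continue
        if a not in pos or b not in pos:
            raise ValidationError(f"pair ({a!r}, {b!r}) outside weight alphabet")
        f[pos[a], pos[b]] += 1
    n = int(f.sum())
    if n < 2:
        raise InsufficientDataError("need >= 2 complete rating pairs")
    p = f / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    w = weights.w
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if pe >= 1.0 - 1e-12:
        # both raters concentrated on a single category: kappa undefined
        return AgreementResult(
            1.0 if po >= 1.0 - 1e-12 else 0.0, 0.0, 1.0, 1.0, float("nan"),
            n, 2 * n, null_value, "cohen_kappa_w",
            p_a=po, p_e=pe, degenerate=True,
            note="chance agreement is 1 (constant raters): kappa undefined",
        )
    kappa = (po - pe) / (1 - pe)
    wbar_row = w @ col  # E over the column margin, per row category
    wbar_col = row @ w
    term = (w * (1 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - po)) ** 2
    var = ((p * term).sum() - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi, pv = _ci_p(kappa, se, null_value, sided)
    return AgreementResult(
        float(kappa), se, lo, hi, pv, n, 2 * n, null_value, "cohen_kappa_w", p_a=po, p_e=pe
    )


def fleiss_kappa(
    matrix: RatingMatrix, null_value: float = 0.0, sided: str = "two"
) -> AgreementResult:
    """Multi-rater (Fleiss-type) kappa, missing-tolerant.

    Chance term p_e = sum_q pi_q^2 with unit-averaged prevalences, which
    reduces to the classical Fleiss formula under complete data.  Provided
    chiefly to demonstrate the prevalence paradox next to AC1.
    """
    cats = matrix.scheme.categories
    r = matrix.counts(cats)
    n_obs = int(r.sum())
    ri = r.sum(axis=1)
    r = r[ri > 0]
    ri = ri[ri > 0]
    n = len(r)
    pa_i, ok = _pairwise_pa(r, np.eye(len(cats)))
    n2 = int(ok.sum())
    if n2 < 2:
        raise InsufficientDataError("need >= 2 units with >= 2 non-NA ratings")
    pa = float(pa_i[ok].mean())
    pi = (r / ri[:, None]).mean(axis=0)
    pe = float((pi**2).sum())
    if pe >= 1.0 - 1e-12:
        return AgreementResult(
            1.0 if pa >= 1.0 - 1e-12 else 0.0, 0.0, 1.0, 1.0, float("nan"),
            n, n_obs, null_value, "fleiss_kappa", p_a=pa, p_e=pe, degenerate=True,
            note="single observed category: kappa undefined",
        )
    kappa = (pa - pe) / (1 - pe)
    k_i = np.where(ok, (n / n2) * (pa_i - pe * ok) / (1 - pe), 0.0)
    pe_i = (r @ pi) / ri
    k_star = k_i - 2 * (1 - kappa) * (pe_i - pe) / (1 - pe)
    var = float(((k_star - kappa) ** 2).sum() / (n * (n - 1))) if n > 1 else 0.0
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi, pv = _ci_p(kappa, se, null_value, sided)
    return AgreementResult(
        float(kappa), se, lo, hi, pv, n, n_obs, null_value, "fleiss_kappa", p_a=pa, p_e=pe
    )


def ac_batch(codes: np.ndarray, kind: str = "identity"):
    """Vectorized Gwet AC over a batch of complete rating matrices.

    ``codes`` is an integer array (reps, n_units, n_raters) of 0-based
    category codes.  Each replicate applies the conservative
    category-exclusion rule before weighting (categories absent from that
    replicate are dropped).  Returns (coef, se) arrays of length reps, with
    NaN for degenerate replicates (a single observed category).

    This is the Monte-Carlo fast path of the power module; it must agree
    with :func:`gwet_ac` replicate-by-replicate.
    """
    codes = np.asarray(codes)
    b, n, k = codes.shape
    qmax = int(codes.max()) + 1
    counts = np.zeros((b, n, qmax), dtype=np.int64)
    np.add.at(counts.reshape(b * n, qmax), (np.arange(b * n)[:, None], codes.reshape(b * n, k)), 1)

    observed = counts.sum(axis=1) > 0  # (b, qmax)
    coef = np.full(b, np.nan)
    se = np.full(b, np.nan)
    # group replicates sharing an observed-category pattern to keep vector shape
    patterns, inverse = np.unique(observed, axis=0, return_inverse=True)
    for g, pat in enumerate(patterns):
        idx = np.nonzero(inverse == g)[0]
        q = int(pat.sum())
        if q < 2:
            continue
        r = counts[np.ix_(idx, np.arange(n), np.nonzero(pat)[0])].astype(float)
        w = build_weights(tuple(str(c) for c in range(q)), kind).w
        rw = r @ w
        pa_i = ((r * rw).sum(axis=2) - k) / (k * (k - 1))  # (m, n)
        pa = pa_i.mean(axis=1)
        pi = r.mean(axis=1) / k  # (m, q)
        tw = w.sum()
        pe = tw / (q * (q - 1)) * (pi * (1 - pi)).sum(axis=1)
        c = (pa - pe) / (1 - pe)
        ac_i = (pa_i - pe[:, None]) / (1 - pe)[:, None]
        pe_i = (tw / (q * (q - 1))) * (r @ (1 - pi)[..., None])[..., 0] / k
        ac_star = ac_i - 2 * (1 - c)[:, None] * (pe_i - pe[:, None]) / (1 - pe)[:, None]
        var = ((ac_star - c[:, None]) ** 2).sum(axis=1) / (n * (n - 1))
        coef[idx] = c
        se[idx] = np.sqrt(np.maximum(var, 0.0))
    return coef, se
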