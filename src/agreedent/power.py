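"""Simulation-based power and sample-size analysis for Gwet's AC2, plus the
closed-form ICC precision sample size.

Rating simulator
----------------
Correlated ordinal ratings are generated by a latent-copy mixture: each
unit draws a latent category L from the marginal distribution pi, and each
rater independently reports L with probability rho or an independent draw
from pi otherwise.  The mechanism preserves the marginal distribution of
every rater exactly for every rho, makes raters exchangeable, and has a
closed-form expected agreement

    E[p_a] = rho^2 + (1 - rho^2) * pi' W pi,

so the asymptotic AC is (E[p_a] - p_e)/(1 - p_e); under uniform marginals
with identity weights this reduces to E[AC1] = rho^2, which anchors the
calibration tests.

Power procedure
---------------
For a design (R raters, Q categories, marginal shape), rho is calibrated
by bisection so the Monte-Carlo mean AC2 hits a target (e.g. 0.6); rating
matrices of n units are then simulated, AC2 and its linearized SE are
estimated per replicate, and power is the proportion of replicates in
which the one-sided normal test of AC2 > null (e.g. 0.4) rejects at level
alpha.  The minimum n on a grid reaching the target power is extracted per
condition.

Skewed marginals are truncated-geometric, pi_q proportional to r^(q-1)
with ratio 0.7 (mass on low stages) or its reverse (mass on high stages).

ICC precision
-------------
:func:`bonett_icc_n` is Bonett's (2002) approximate sample size for a
desired ICC confidence-interval width with k raters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .agreement import ac_batch, fleiss_kappa
from .exceptions import CalibrationError, ValidationError
from .study import RatingMatrix, StagingScheme
from .weights import build_weights

MARGINAL_NAMES = ("uniform", "skew_low", "skew_high")
SKEW_RATIO = 0.7
DEFAULT_N_GRID = (5, 10, 15, 20, 25, 30, 40, 50)


def marginal_probs(marginal, n_categories: int) -> np.ndarray:
    """Category probabilities for a named marginal shape (or pass-through)."""
    if isinstance(marginal, str):
        if marginal == "uniform":
            pi = np.ones(n_categories)
        elif marginal == "skew_low":
            pi = SKEW_RATIO ** np.arange(n_categories)
        elif marginal == "skew_high":
            pi = SKEW_RATIO ** np.arange(n_categories)[::-1]
        else:
            raise ValidationError(f"unknown marginal {marginal!r}; use {MARGINAL_NAMES}")
        return pi / pi.sum()
    pi = np.asarray(marginal, dtype=float)
    if pi.ndim != 1 or len(pi) != n_categories:
        raise ValidationError("marginal length must equal n_categories")
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
        raise ValidationError("marginal probabilities must be >= 0 and sum to 1")
    return pi / pi.sum()


@dataclass(frozen=True)
class SimDesign:
    """One simulation condition for the rating generator."""

    n_categories: int
    n_raters: int = 9
    marginal: object = "uniform"
    rho: float = 0.0
    n_units: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [0, 1]")
        marginal_probs(self.marginal, self.n_categories)  # validate

    @property
    def pi(self) -> np.ndarray:
        return marginal_probs(self.marginal, self.n_categories)


def simulate_codes(
    design: SimDesign, reps: int = 1, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Integer category codes, shape (reps, n_units, n_raters)."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    pi = design.pi
    b, n, k = reps, design.n_units, design.n_raters
    latent = rng.choice(design.n_categories, size=(b, n, 1), p=pi)
    noise = rng.choice(design.n_categories, size=(b, n, k), p=pi)
    copy = rng.random((b, n, k)) < design.rho
    return np.where(copy, latent, noise)


def simulate_ratings(design: SimDesign, rng: np.random.Generator | None = None) -> RatingMatrix:
    """One simulated study as a RatingMatrix with a generic ordinal scheme."""
    codes = simulate_codes(design, reps=1, rng=rng)[0]
    cats = tuple(str(c + 1) for c in range(design.n_categories))
    scheme = StagingScheme(f"SIM{design.n_categories}", cats, False, frozenset({38}))
    cells = np.array([[cats[c] for c in row] for row in codes], dtype=object)
    return RatingMatrix(
        list(range(design.n_units)), list(range(design.n_raters)), cells, scheme
    )


def expected_ac(rho: float, pi, weight_kind: str = "identity") -> float:
    """Closed-form large-n AC for the latent-copy simulator."""
    pi = np.asarray(pi, dtype=float)
    q = len(pi)
    if q < 2:
        raise ValidationError("need >= 2 categories")
    w = build_weights(tuple(str(i) for i in range(q)), weight_kind)
    s = float(pi @ w.w @ pi)
    pe = float(w.total / (q * (q - 1)) * (pi * (1 - pi)).sum())
    pa = rho**2 + (1 - rho**2) * s
    return (pa - pe) / (1 - pe)


def rho_for_expected_ac(target: float, pi, weight_kind: str = "identity") -> float:
    """Invert :func:`expected_ac` (the large-n anchor for calibration)."""
    pi = np.asarray(pi, dtype=float)
    q = len(pi)
    w = build_weights(tuple(str(i) for i in range(q)), weight_kind)
    s = float(pi @ w.w @ pi)
    pe = float(w.total / (q * (q - 1)) * (pi * (1 - pi)).sum())
    pa_target = pe + target * (1 - pe)
    if pa_target < s:
        raise CalibrationError(f"target {target} is below the chance level of this design")
    if s >= 1.0:
        raise CalibrationError("degenerate marginal: chance agreement is already 1")
    return float(np.sqrt(min((pa_target - s) / (1 - s), 1.0)))


def _mean_ac(design: SimDesign, weight_kind: str, reps: int, rng) -> float:
    codes = simulate_codes(design, reps=reps, rng=rng)
    coef, _ = ac_batch(codes, weight_kind)
    coef = coef[np.isfinite(coef)]
    if len(coef) == 0:
        raise CalibrationError("all replicates degenerate; increase n_units")
    return float(coef.mean())


def calibrate_rho(
    target_ac: float,
    design: SimDesign,
    weight_kind: str = "ordinal",
    reps: int = 500,
    tol: float = 0.005,
    max_iter: int = 25,
) -> float:
    """Bisect rho so the Monte-Carlo mean AC matches ``target_ac``.

    The mean AC is monotone increasing in rho; the closed-form inverse
    seeds the bracket.  Deterministic given ``design.seed``.
    """
    if not 0.0 < target_ac < 1.0:
        raise CalibrationError("target AC must lie strictly in (0, 1)")
    pi = design.pi
    rho_for_expected_ac(target_ac, pi, weight_kind)  # raises if unattainable
    rng = np.random.default_rng(design.seed)
    lo, hi = 0.0, 1.0
    rho = rho_for_expected_ac(target_ac, pi, weight_kind)
    for _ in range(max_iter):
        m = _mean_ac(replace(design, rho=rho), weight_kind, reps, rng)
        if abs(m - target_ac) <= tol:
            return rho
        if m < target_ac:
            lo = rho
        else:
            hi = rho
        rho = 0.5 * (lo + hi)
    return rho


def estimate_power(
    design: SimDesign,
    weight_kind: str = "ordinal",
    null_ac: float = 0.4,
    alpha: float = 0.05,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
):
    """Rejection proportion of the one-sided AC test across replicates.

    Returns (power, mc_se, n_degenerate).  Degenerate replicates (single
    observed category) are skipped and counted.
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    codes = simulate_codes(design, reps=reps, rng=rng)
    coef, se = ac_batch(codes, weight_kind)
    valid = np.isfinite(coef)
    n_deg = int((~valid).sum())
    coef, se = coef[valid], se[valid]
    zcrit = stats.norm.ppf(1 - alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (coef - null_ac) / np.where(se > 0, se, 1.0), np.inf * np.sign(coef - null_ac))
    reject = z > zcrit
    power = float(reject.mean()) if len(reject) else float("nan")
    mc_se = float(np.sqrt(power * (1 - power) / len(reject))) if len(reject) else float("nan")
    return power, mc_se, n_deg


@dataclass
class PowerGrid:
    """Per-condition rejection proportions and extracted minimum n."""

    conditions: list  # (marginal, n_categories)
    n_grid: tuple
    power: dict  # (marginal, q, n) -> proportion
    rho: dict  # (marginal, q) -> calibrated rho
    min_n: dict  # (marginal, q) -> int | None
    alpha: float
    target_ac: float
    null_ac: float
    target_power: float
    reps: int
    n_raters: int
    weight_kind: str
    seed: int

    @property
    def recommended_n(self):
        """Largest per-condition minimum n (None if any condition unattained)."""
        vals = list(self.min_n.values())
        if any(v is None for v in vals):
            return None
        return max(vals)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "target_ac": self.target_ac,
            "null_ac": self.null_ac,
            "target_power": self.target_power,
            "reps": self.reps,
            "n_raters": self.n_raters,
            "weight_kind": self.weight_kind,
            "seed": self.seed,
            "n_grid": list(self.n_grid),
            "conditions": [
                {
                    "marginal": m,
                    "n_categories": q,
                    "rho": self.rho[(m, q)],
                    "power": {str(n): self.power[(m, q, n)] for n in self.n_grid
                              if (m, q, n) in self.power},
                    "min_n": self.min_n[(m, q)],
                }
                for (m, q) in self.conditions
            ],
            "recommended_n": self.recommended_n,
        }


def min_n_for_power(
    conditions=None,
    n_grid=DEFAULT_N_GRID,
    target_power: float = 0.8,
    alpha: float = 0.05,
    weight_kind: str = "ordinal",
    target_ac: float = 0.6,
    null_ac: float = 0.4,
    n_raters: int = 9,
    reps: int = 1000,
    calib_reps: int = 500,
    seed: int = 0,
    calib_n_units: int = 100,
) -> PowerGrid:
    """Full power grid and minimum sample size per condition.

    Default conditions are the study design: 9 raters, 7/8/10 categories,
    uniform and both skewed marginals, AC2 with ordinal weights, target
    mean AC2 0.6 against a null of 0.4, one-sided alpha 0.05.
    """
    if conditions is None:
        conditions = [(m, q) for m in MARGINAL_NAMES for q in (7, 8, 10)]
    n_grid = tuple(sorted(n_grid))
    ss = np.random.SeedSequence(seed)
    power_map, rho_map, minn_map = {}, {}, {}
    for (marginal, q), child in zip(conditions, ss.spawn(len(conditions))):
        sub = child.generate_state(2)
        base = SimDesign(
            n_categories=q, n_raters=n_raters, marginal=marginal,
            n_units=calib_n_units, seed=int(sub[0] % (2**31)),
        )
        rho = calibrate_rho(target_ac, base, weight_kind, reps=calib_reps)
        rho_map[(marginal, q)] = rho
        rng = np.random.default_rng(int(sub[1] % (2**31)))
        min_n = None
        for n in n_grid:
            design = replace(base, rho=rho, n_units=n)
            pw, _, _ = estimate_power(design, weight_kind, null_ac, alpha, reps, rng=rng)
            power_map[(marginal, q, n)] = pw
            if min_n is None and pw >= target_power:
                min_n = n
                break  # power is monotone in n up to MC noise
        minn_map[(marginal, q)] = min_n
    return PowerGrid(
        conditions=list(conditions), n_grid=n_grid, power=power_map, rho=rho_map,
        min_n=minn_map, alpha=alpha, target_ac=target_ac, null_ac=null_ac,
        target_power=target_power, reps=reps, n_raters=n_raters,
        weight_kind=weight_kind, seed=seed,
    )


def bonett_icc_n(
    rho_plan: float, k_raters: int, halfwidth: float, confidence: float = 0.95
) -> int:
    """Bonett's sample size for an ICC confidence interval of given width.

    n = ceil( 8 z^2 (1-rho)^2 (1+(k-1)rho)^2 / (k (k-1) w^2) + 1 ), with w
    the full interval width (2 x halfwidth).
    """
    if not 0.0 < rho_plan < 1.0:
        raise ValueError("planning ICC must lie strictly in (0, 1)")
    if k_raters < 2:
        raise ValueError("need k >= 2 raters")
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2)
    w = 2.0 * halfwidth
    n = (
        8.0 * z**2 * (1 - rho_plan) ** 2 * (1 + (k_raters - 1) * rho_plan) ** 2
        / (k_raters * (k_raters - 1) * w**2)
        + 1.0
    )
    return int(np.ceil(n))


def precision_n_simulated(
    coefficient: str,
    expected: float,
    halfwidth: float,
    n_raters: int = 9,
    n_categories: int = 7,
    marginal="uniform",
    weight_kind: str = "ordinal",
    n_grid=DEFAULT_N_GRID,
    reps: int = 300,
    seed: int = 0,
):
    """Smallest grid n whose median 95% CI half-width is <= ``halfwidth``.

    A simulation-based precision (CI-width) sample-size search for
    ``kappa`` (multi-rater Fleiss-type), ``ac1`` or ``ac2``, with the
    rating correlation calibrated to the expected coefficient value.
    Returns (n, diagnostics); n is None if no grid point reaches the
    precision.
    """
    if coefficient not in ("kappa", "ac1", "ac2"):
        raise ValueError("coefficient must be one of kappa, ac1, ac2")
    if not 0.0 < expected < 1.0:
        raise ValueError("expected coefficient must lie in (0, 1)")
    kind = "identity" if coefficient in ("kappa", "ac1") else weight_kind
    ss = np.random.SeedSequence(seed).generate_state(2)
    base = SimDesign(
        n_categories=n_categories, n_raters=n_raters, marginal=marginal,
        n_units=100, seed=int(ss[0] % (2**31)),
    )
    if coefficient == "kappa":
        rho = _calibrate_rho_kappa(expected, base, reps=min(reps, 200))
    else:
        rho = calibrate_rho(expected, base, kind, reps=max(reps, 300))
    rng = np.random.default_rng(int(ss[1] % (2**31)))
    diagnostics = {"rho": rho, "median_halfwidth": {}}
    chosen = None
    for n in sorted(n_grid):
        design = replace(base, rho=rho, n_units=n)
        if coefficient == "kappa":
            hws = []
            for _ in range(reps):
                m = simulate_ratings(design, rng=rng)
                res = fleiss_kappa(m)
                hws.append((res.ci_high - res.ci_low) / 2 if not res.degenerate else np.nan)
            hw = float(np.nanmedian(hws))
        else:
            codes = simulate_codes(design, reps=reps, rng=rng)
            coef, se = ac_batch(codes, kind)
            hw = float(np.nanmedian(1.959964 * se))
        diagnostics["median_halfwidth"][n] = hw
        if chosen is None and np.isfinite(hw) and hw <= halfwidth:
            chosen = n
            break
    return chosen, diagnostics


def _calibrate_rho_kappa(target: float, design: SimDesign, reps: int = 200) -> float:
    """Bisect rho on the Monte-Carlo mean Fleiss kappa (loop-based)."""
    rng = np.random.default_rng(design.seed)

    def mean_kappa(rho):
        d = replace(design, rho=rho)
        vals = []
        for _ in range(reps):
            res = fleiss_kappa(simulate_ratings(d, rng=rng))
            if not res.degenerate:
                vals.append(res.coefficient)
        if not vals:
            raise CalibrationError("all replicates degenerate")
        return float(np.mean(vals))

    lo, hi = 0.0, 1.0
    rho = float(np.sqrt(target))
    for _ in range(20):
        m = mean_kappa(rho)
        if abs(m - target) <= 0.01:
            return rho
        if m < target:
            lo = rho
        else:
            hi = rho
        rho = 0.5 * (lo + hi)
    return rho
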