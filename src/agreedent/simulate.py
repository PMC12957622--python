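"""Synthetic multi-observer dental-staging study generator.

The raw radiograph ratings behind the study design this package targets
(50 subjects aged 14-23.99, 9 calibrated observers, 2 sessions two weeks
apart, third molars FDI 18/28/38/48, methods KUL/DEM/GHK/I3M) are not
deposited anywhere, so the pipeline is exercised on synthetic data whose
*published* statistical structure is reproduced:

* per-(method, tooth) stage marginal distributions and NA proportions set
  to the published descriptive table (450 session-1 ratings per tooth);
* I3M subject truth drawn log-normal, parameterized so the median and
  quartiles match the published 0.27 (0.18-0.45) / 0.26 (0.17-0.42);
* inter-observer dependence by the latent-copy mechanism of the power
  module, with the per-method correlation set by default so the expected
  ordinal-weighted AC2 matches the published overall coefficients
  (KUL 0.868, DEM 0.918, GHK 0.914);
* session 2 repeats the session-1 rating with probability
  ``intra_repeat_agreement`` (default 0.95) and is regenerated otherwise;
  I3M session-2 readings are always fresh noisy measurements of the same
  truth (identical repeated metric measurements are practically
  impossible).

NA responses are imposed independently of stage at the published
per-tooth rates; the physical causes of unassessability are not modeled.
Every generating parameter is recorded in a truth dictionary so that
pipeline estimates can be compared against known values
(:func:`recover_parameters`).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .study import DEM, GHK, I3M, KUL, SCHEMES, RatingTable, SubjectMeta
from .weights import build_weights

#: session-1 stage counts per (method, tooth) out of 450 = 50 subjects x 9
#: observers, conditional part (non-NA), plus the NA count.
STAGE_COUNTS = {
    ("KUL", 38): ([77, 75, 58, 112, 78, 35, 14], 1),
    ("KUL", 48): ([74, 66, 66, 102, 81, 34, 24], 3),
    ("DEM", 18): ([0, 0, 0, 46, 122, 135, 85, 41], 21),
    ("DEM", 28): ([0, 0, 0, 48, 124, 136, 82, 39], 21),
    ("DEM", 38): ([0, 0, 4, 74, 115, 166, 70, 21], 0),
    ("DEM", 48): ([0, 0, 3, 68, 116, 147, 82, 30], 4),
    ("GHK", 18): ([0, 0, 5, 54, 88, 97, 69, 46, 35, 34], 22),
    ("GHK", 28): ([0, 0, 5, 57, 85, 100, 67, 49, 31, 36], 20),
    ("GHK", 38): ([0, 1, 12, 64, 101, 82, 91, 59, 23, 16], 1),
    ("GHK", 48): ([0, 1, 8, 64, 99, 86, 76, 61, 24, 27], 4),
}

#: I3M median and quartiles per tooth, plus NA count out of 450.
I3M_SUMMARY = {
    38: {"median": 0.27, "q1": 0.18, "q3": 0.45, "na": 1},
    48: {"median": 0.26, "q1": 0.17, "q3": 0.42, "na": 7},
}

#: published overall inter-observer AC2 (ordinal weights) per staging method
DEFAULT_TARGET_AC2 = {"KUL": 0.868, "DEM": 0.918, "GHK": 0.914}

#: published overall inter-observer ICC for the continuous index
DEFAULT_TARGET_ICC = 0.986

_Z_QUARTILE = 0.6744897501960817  # standard normal 75th percentile


def _stage_marginal(method: str, tooth: int) -> np.ndarray:
    counts, _ = STAGE_COUNTS[(method, tooth)]
    c = np.asarray(counts, dtype=float)
    return c / c.sum()


def _na_rate(method: str, tooth: int) -> float:
    if method == "I3M":
        return I3M_SUMMARY[tooth]["na"] / 450.0
    counts, na = STAGE_COUNTS[(method, tooth)]
    return na / (sum(counts) + na)


def _default_rho(method: str, target: float) -> float:
    """Correlation hitting the target pooled AC2 (ordinal weights).

    The pooled ("Overall") coefficient stacks (subject, tooth) units, so
    its expected observed agreement is the across-teeth mean of the
    per-tooth weighted chance matches, while its chance term comes from
    the across-teeth mean prevalence vector.  Solving
    target = (rho^2 + (1 - rho^2) s_bar - p_e) / (1 - p_e) for rho gives
    the generating correlation.
    """
    teeth = sorted(SCHEMES[method].applicable_teeth)
    per_tooth = [
        np.asarray(STAGE_COUNTS[(method, t)][0], float) for t in teeth
    ]
    per_tooth = [p / p.sum() for p in per_tooth]
    support = np.sum(per_tooth, axis=0) > 0  # conservative exclusion
    per_tooth = [p[support] for p in per_tooth]
    q = int(support.sum())
    w = build_weights(tuple(str(i) for i in range(q)), "ordinal")
    s_bar = float(np.mean([p @ w.w @ p for p in per_tooth]))
    pi_bar = np.mean(per_tooth, axis=0)
    pe = float(w.total / (q * (q - 1)) * (pi_bar * (1 - pi_bar)).sum())
    pa_target = pe + target * (1 - pe)
    if pa_target < s_bar or s_bar >= 1.0:
        raise ValidationError(f"target AC2 {target} unattainable for {method}")
    return float(np.sqrt(min((pa_target - s_bar) / (1 - s_bar), 1.0)))


def _i3m_lognormal_params(tooth: int) -> tuple[float, float]:
    s = I3M_SUMMARY[tooth]
    mu = float(np.log(s["median"]))
    sigma = float((np.log(s["q3"]) - np.log(s["q1"])) / (2 * _Z_QUARTILE))
    return mu, sigma


@dataclass
class StudyConfig:
    """Generating parameters of one synthetic study (defaults = the design
    and published descriptive structure of the real 50 x 9 study)."""

    n_subjects: int = 50
    n_observers: int = 9
    sessions: int = 2
    methods: tuple = (KUL, DEM, GHK, I3M)
    stage_marginals: dict = field(default_factory=dict)  # (method, tooth) -> probs
    na_rate: dict = field(default_factory=dict)  # (method, tooth) -> prob
    inter_rho: dict = field(default_factory=dict)  # method -> rho
    target_ac2: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_AC2))
    intra_repeat_agreement: float = 0.95
    i3m_params: dict = field(default_factory=dict)  # tooth -> (mu, sigma, noise_sd)
    age_range: tuple = (14.0, 23.99)
    n_male: int = 19
    n_female: int = 31
    seed: int = 0

    def __post_init__(self):
        if self.sessions != 2:
            raise ValidationError("the study design has exactly 2 sessions")
        if self.n_male + self.n_female != self.n_subjects:
            raise ValidationError("sex counts must sum to n_subjects")
        if not 0.0 <= self.intra_repeat_agreement <= 1.0:
            raise ValidationError("intra_repeat_agreement must lie in [0, 1]")
        for scheme in self.methods:
            for tooth in sorted(scheme.applicable_teeth):
                key = (scheme.method_id, tooth)
                if scheme.is_continuous:
                    if tooth not in self.i3m_params:
                        mu, sigma = _i3m_lognormal_params(tooth)
                        noise_sd = sigma * float(
                            np.sqrt(1.0 / DEFAULT_TARGET_ICC - 1.0)
                        )
                        self.i3m_params[tooth] = (mu, sigma, noise_sd)
                    if key not in self.na_rate:
                        self.na_rate[key] = _na_rate(*key)
                    continue
                if key not in self.stage_marginals:
                    self.stage_marginals[key] = _stage_marginal(*key)
                pi = np.asarray(self.stage_marginals[key], dtype=float)
                if len(pi) != scheme.n_categories or (pi < 0).any():
                    raise ValidationError(f"bad marginal for {key}")
                if not np.isclose(pi.sum(), 1.0):
                    raise ValidationError(f"marginal for {key} must sum to 1")
                if key not in self.na_rate:
                    self.na_rate[key] = _na_rate(*key)
                if not 0.0 <= self.na_rate[key] <= 1.0:
                    raise ValidationError(f"bad NA rate for {key}")
            if not scheme.is_continuous and scheme.method_id not in self.inter_rho:
                self.inter_rho[scheme.method_id] = _default_rho(
                    scheme.method_id, self.target_ac2[scheme.method_id]
                )


def _draw_codes(rng, latent, pi, rho, n_obs):
    """Session ratings: copy the latent stage w.p. rho, else independent."""
    n = len(latent)
    noise = rng.choice(len(pi), size=(n, n_obs), p=pi)
    copy = rng.random((n, n_obs)) < rho
    return np.where(copy, latent[:, None], noise)


def generate_study(config: StudyConfig | None = None):
    """Generate (RatingTable, [SubjectMeta], truth dict), seed-reproducible."""
    config = config if config is not None else StudyConfig()
    rng = np.random.default_rng(config.seed)
    subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    observers = [str(j + 1) for j in range(config.n_observers)]

    # subject metadata: ages uniform over the design range, fixed sex split
    ages = rng.uniform(*config.age_range, size=config.n_subjects)
    sexes = np.array(["M"] * config.n_male + ["F"] * config.n_female)
    rng.shuffle(sexes)
    base = _dt.date(2023, 1, 1)
    metas = []
    for sid, age, sex in zip(subjects, ages, sexes):
        exposure = base + _dt.timedelta(days=int(rng.integers(0, 365)))
        dob = exposure - _dt.timedelta(days=int(round(age * 365.25)))
        metas.append(
            SubjectMeta(sid, str(sex), dob, exposure, (exposure - dob).days / 365.25)
        )

    records = []
    truth = {
        "seed": config.seed,
        "inter_rho": dict(config.inter_rho),
        "target_ac2": dict(config.target_ac2),
        "intra_repeat_agreement": config.intra_repeat_agreement,
        "stage_marginals": {f"{m}:{t}": list(map(float, v))
                           for (m, t), v in config.stage_marginals.items()},
        "na_rate": {f"{m}:{t}": float(v) for (m, t), v in config.na_rate.items()},
        "i3m_params": {t: tuple(map(float, v)) for t, v in config.i3m_params.items()},
        "i3m_target_icc": {},
        "latent": {},
    }

    for scheme in config.methods:
        for tooth in sorted(scheme.applicable_teeth):
            key = (scheme.method_id, tooth)
            na_p = config.na_rate[key]
            if scheme.is_continuous:
                mu, sigma, noise_sd = config.i3m_params[tooth]
                truth["i3m_target_icc"][tooth] = sigma**2 / (sigma**2 + noise_sd**2)
                tvals = np.exp(rng.normal(mu, sigma, size=config.n_subjects))
                truth["latent"][f"I3M:{tooth}"] = tvals.tolist()
                for session in (1, 2):
                    noise = rng.normal(0.0, noise_sd, (config.n_subjects, config.n_observers))
                    vals = np.round(tvals[:, None] * np.exp(noise), 4)
                    na = rng.random((config.n_subjects, config.n_observers)) < na_p
                    for i, sid in enumerate(subjects):
                        for j, obs in enumerate(observers):
                            records.append(
                                (sid, obs, session, tooth, "I3M",
                                 None if na[i, j] else float(vals[i, j]))
                            )
                continue

            pi = np.asarray(config.stage_marginals[key], dtype=float)
            rho = config.inter_rho[scheme.method_id]
            latent = rng.choice(scheme.n_categories, size=config.n_subjects, p=pi)
            truth["latent"][f"{scheme.method_id}:{tooth}"] = latent.tolist()
            s1 = _draw_codes(rng, latent, pi, rho, config.n_observers)
            na1 = rng.random(s1.shape) < na_p
            # session 2: exact repeat of session 1 (value or NA) w.p.
            # intra_repeat_agreement, fresh draw otherwise
            repeat = rng.random(s1.shape) < config.intra_repeat_agreement
            s2_new = _draw_codes(rng, latent, pi, rho, config.n_observers)
            na2_new = rng.random(s1.shape) < na_p
            s2 = np.where(repeat, s1, s2_new)
            na2 = np.where(repeat, na1, na2_new)
            for i, sid in enumerate(subjects):
                for j, obs in enumerate(observers):
                    v1 = None if na1[i, j] else scheme.categories[s1[i, j]]
                    v2 = None if na2[i, j] else scheme.categories[s2[i, j]]
                    records.append((sid, obs, 1, tooth, scheme.method_id, v1))
                    records.append((sid, obs, 2, tooth, scheme.method_id, v2))

    df = pd.DataFrame(
        records,
        columns=["subject_id", "observer_id", "session", "tooth", "method", "value"],
    ).sort_values(["method", "tooth", "session", "subject_id", "observer_id"]).reset_index(
        drop=True
    )
    table = RatingTable(df, {s.method_id: s for s in config.methods})
    return table, metas, truth


def recover_parameters(table: RatingTable, truth: dict) -> dict:
    """Run the full pipeline on a generated table and compare to the truth.

    Returns, per staging method, the estimated overall AC2 (ordinal
    weights) next to the generating target; per I3M tooth, the estimated
    inter-observer ICC next to the variance-component truth; and the mean
    intra-observer kappa next to the repeat probability.
    """
    from .agreement import cohen_kappa_weighted, gwet_ac
    from .icc import icc_absolute
    from .na import na_agreement
    from .study import pivot_to_matrix, session_pairs
    from .weights import weights_for_matrix

    report = {"inter_ac2": {}, "inter_icc": {}, "intra_kappa_mean": {}, "na_ac1": {}}
    for method in table.methods():
        scheme = table.schemes[method]
        m1 = pivot_to_matrix(table, method, session=1, pooling="overall")
        report["na_ac1"][method] = na_agreement(m1).ac1.coefficient
        if scheme.is_continuous:
            for tooth in sorted(scheme.applicable_teeth):
                mt = pivot_to_matrix(table, method, teeth={tooth}, session=1,
                                     pooling="per_tooth")
                res = icc_absolute(mt)
                report["inter_icc"][tooth] = {
                    "estimate": res.icc,
                    "truth": truth["i3m_target_icc"][tooth],
                }
            continue
        w = weights_for_matrix(m1, "ordinal")
        res = gwet_ac(m1, w)
        report["inter_ac2"][method] = {
            "estimate": res.coefficient,
            "target": truth["target_ac2"][method],
            "rho": truth["inter_rho"][method],
        }
        kappas = []
        for obs in table.observers():
            for tooth in sorted(scheme.applicable_teeth):
                pairs = [(a, b) for a, b, ok in session_pairs(table, obs, method, tooth) if ok]
                cats = tuple(
                    c for c in scheme.categories
                    if any(c in p for p in pairs)
                )
                if len(cats) < 2:
                    continue
                res_k = cohen_kappa_weighted(pairs, build_weights(cats, "ordinal"))
                if not res_k.degenerate:
                    kappas.append(res_k.coefficient)
        report["intra_kappa_mean"][method] = {
            "estimate": float(np.mean(kappas)),
            "repeat_probability": truth["intra_repeat_agreement"],
        }
    return report
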