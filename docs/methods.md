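# Methods

## Data model

A rating study is a long-format table with one record per (subject,
observer, session, tooth, method). Four assessment systems are built in:
Kullman (KUL, ordinal stages 1–7, mandibular third molars FDI 38/48 only
— the scheme has no crown-development stages), Demirjian (DEM, stages
A–H, all four third molars), Gleiser & Hunt as modified by Köhler (GHK,
stages 1–10, all four), and the continuous third molar maturity index
(I3M, a non-negative open-apex/length ratio defined on mandibular third
molars). A rating is a stage label, a non-negative real, or NA ("not
assessable"). Stage labels are stored as strings; the 0-based position in
the scheme's alphabet is the only numeric handle used downstream, which
avoids any A-vs-1 ambiguity across methods. Dates are ISO-8601 and
decimal age is day count / 365.25 — the standard forensic convention.

Analyses run on units × observers matrices. The analysis unit for pooled
("Overall" and per-jaw) coefficients is the **(subject, tooth) pair**:
under this convention a four-tooth method contributes 50 × 4 = 200 units
and 1800 session-1 observations before NA exclusion, matching the
observation totals such studies report. Inter-observer coefficients use
session 1 only (the first, uninfluenced evaluation); intra-observer
coefficients pair the two sessions per observer.

## Agreement coefficients

All coefficients have the form (p_a − p_e)/(1 − p_e). p_a is the mean
over informative units (≥ 2 non-NA ratings) of the weighted proportion of
agreeing ordered rater pairs, with agreement weights w_kl ∈ [0, 1],
w_kk = 1. Weight kinds: identity; linear 1 − |k−l|/(Q−1); quadratic
1 − (k−l)²/(Q−1)²; ordinal 1 − C(|k−l|+1, 2)/C(Q, 2) (the
pairs-combination weighting for ordered stages, the default).

- **Weighted Cohen's kappa** (two raters / two sessions): p_e from the
  product of the two marginal distributions; SE by the
  Fleiss–Cohen–Everitt large-sample variance (cross-checked against
  statsmodels in the tests). NA-bearing pairs are excluded and counted.
- **Fleiss-type kappa** (multi-rater): p_e = Σ_q π_q², with π_q the
  unit-averaged classification proportion; reduces to the classical
  Fleiss formula under complete data. Included to demonstrate the
  prevalence paradox, not for headline reporting.
- **Gwet's AC1/AC2**: p_e = (T_w/(Q(Q−1))) Σ_q π_q(1−π_q), with T_w the
  sum of all weights. Identity weights give AC1 (T_w = Q); AC2 is the
  weighted generalization and coincides with AC1 for Q = 2, since
  ordinal weights reduce to identity on a binary alphabet.

Missing data are handled observation-wise: NA cells are dropped within a
unit; units keep contributing to the prevalences π_q while they retain at
least one rating, and to p_a while they retain two. Variances come from
the unit-level linearization of the estimator (influence form: per-unit
coefficient contributions corrected for the estimated chance term, summed
over units); the tests check this SE against a delete-one-unit jackknife.
No finite-population correction is applied. Confidence intervals are
normal-theory ±1.96 SE truncated to [−1, 1]; p-values are two-sided by
default and one-sided when testing against a planning null (power
analysis). Degenerate inputs (a single observed category, or two constant
raters) return a flagged result rather than raising, so batch pipelines
over many teeth continue.

**Category exclusion.** Weights for an analysis matrix are built over the
categories actually used in that matrix, applied per analyzed table (per
method × pooling level). For the realistic case — unused stages at the
edges of the alphabet, e.g. crown stages A–C never observed in a
late-adolescent sample — exclusion leaves ordinal distances unchanged
while shrinking Q, so every surviving pairwise weight shrinks: the
penalty for observed discrepancies is amplified (conservative). Dropping
a never-used *interior* stage instead shortens ordinal distances and can
raise weights; the conservatism guarantee (and its test) is therefore
stated for contiguous observed ranges.

## ICC for continuous measurements

The continuous I3M uses the two-way, absolute-agreement, single-measure
intraclass correlation, ICC(A,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E +
(k/n)(MS_C − MS_E)) from the additive two-way ANOVA (subjects × raters).
The "two-way mixed" label shares this point estimate with the two-way
random form and differs only in interpretation. Confidence intervals are
the standard F-based interval for this form (cross-checked against
pingouin's ICC(A,1) row); the p-value tests MS_R/MS_E against 1. Rows
with any missing cell are deleted listwise to keep the ANOVA balanced,
and the dropped count is reported. Exact agreement (ICC = 1) returns the
degenerate interval [1, 1].

## NA concordance

Whether observers agree on which teeth are unassessable is analyzed as
its own binary agreement problem: every cell is recoded NA / not-NA (no
missingness remains by construction, so the observation total is exactly
units × raters) and unweighted AC1 is computed. AC1 is the right
instrument here because NA is deliberately rare — the prevalence-imbalance
regime where kappa-type coefficients collapse. A descriptive audit flags
any observer whose NA proportion exceeds 5%; it is a report flag, not a
gate.

## Rating simulator, calibration, power

Correlated ordinal ratings are simulated by a latent-copy mixture: a unit
draws a latent category L ~ π, and each rater independently reports L
with probability ρ or a fresh draw from π otherwise. The mechanism was
chosen because (i) every rater's marginal distribution is exactly π for
all ρ, (ii) raters are exchangeable, and (iii) the expected pairwise
weighted agreement has the closed form ρ² + (1−ρ²)·πᵀWπ, so the large-n
coefficient is available analytically — under uniform marginals with
identity weights it reduces to E[AC1] = ρ², which anchors the calibration
tests. Note that with non-identity weights and skewed marginals the
ρ = 0 coefficient is not zero (independent raters already share weighted
agreement beyond the AC chance term), so targets below that baseline are
rejected as uncalibratable.

ρ is calibrated to a target mean AC2 by bisection on the Monte-Carlo mean
(500 replicates per evaluation, tolerance 0.005, closed-form inverse as
the starting point; deterministic given the seed). Power for a design is
the proportion of replicates in which the one-sided normal test
(AC2 − null)/SE > z_{1−α} rejects; degenerate replicates are skipped and
counted. The sample-size search walks an ascending grid — default
{5, 10, 15, 20, 25, 30, 40, 50}, 1000 replicates per point, α = 0.05
one-sided — and extracts the smallest n with power ≥ 0.8 per condition;
the recommended n is the maximum over conditions. Skewed marginals are
truncated-geometric, π_q ∝ 0.7^(q−1) (and reversed), a simple one-knob
family for "skewed to lower/larger stages". The Monte-Carlo inner loop is
a vectorized batch AC2 path that applies the same per-replicate category
exclusion as the general estimator; the tests require exact
(1e−12-level) agreement between the two routes.

Two precision-based (CI-width) sample sizes complement the power search:
Bonett's closed form for the ICC, n = ⌈8z²(1−ρ)²(1+(k−1)ρ)²/(k(k−1)w²)
+ 1⌉ with w the full interval width, and a generic simulated search
(`precision_n_simulated`) returning the smallest grid n whose median 95%
CI half-width meets a target, for multi-rater kappa, AC1 or AC2. The
simulated search is deliberately generic: a closed-form multi-rater kappa
planning calculation requires committing to specific skewed category
probabilities, and no single canonical choice exists, so the package
exposes the precision criterion itself instead of one fixed table.

## Synthetic study generator

The generator emulates a 50-subject (ages uniform on 14–23.99, 19 male /
31 female), 9-observer, 2-session design. Per (method, tooth), stage
marginals and NA rates default to the published session-1 descriptive
distribution of the target study design (450 ratings per tooth); I3M
truth is log-normal with location/scale matched to the published median
and quartiles (median 0.27, Q1–Q3 0.18–0.45 on tooth 38; 0.26,
0.17–0.42 on tooth 48), observer readings are truth × log-normal noise
with the noise SD set so the variance-component ICC is 0.986, and
readings are rounded to 4 decimals. Inter-observer dependence uses the
latent-copy mechanism with a per-method ρ solved in closed form so the
expected pooled ordinal-weighted AC2 equals the published overall
coefficients (KUL 0.868, DEM 0.918, GHK 0.914); because the pooled
statistic mixes per-tooth marginals, the solver uses the across-teeth
mean of πᵗWπ and the pooled prevalence vector. Session 2 repeats the
session-1 response (value or NA) with probability 0.95 and is freshly
regenerated otherwise; I3M session-2 readings are always new noisy
measurements, reflecting that identical repeated metric measurements are
practically impossible. NA is imposed independently of stage at the
published per-tooth rates.

What the generator does *not* emulate: the physical causes of
unassessability (so NA responses are independent across observers, where
real distorted radiographs would produce correlated NAs), any
age-vs-stage dependence (reliability analysis never uses chronological
age), and observer-specific bias or experience effects (all observers are
exchangeable). Passing tests on synthetic data therefore demonstrate the
correctness of the estimators and the internal consistency of the
pipeline at the real study's scale and marginal structure — not the
substantive reliability of any staging method on real radiographs.

At the study's own scale the pooled AC2 of one synthetic replicate has a
Monte-Carlo spread of roughly ±0.02 (SD) around its target, and the
effective alphabet can vary with the seed when a stage has published
probability below about 1%; the recovery tests budget for this.

## Numerical and design choices

- α = 0.05 one-sided for the AC2 power test; targets 0.6 (expected) and
  0.4 (null) are the conservative planning values of the target design.
- Simulation reps default to 1000 (power / analytic-limit checks) and
  500 (calibration evaluations); the acceptance script uses 1000.
  Problem sizes in the tests (e.g. n = 200 units for limit checks,
  n = 500 × 9 for ICC recovery) were chosen so Monte-Carlo error sits
  well inside the asserted tolerances.
- Ties/edge cases: p_e = 1 (constant raters) and single-category
  alphabets yield flagged degenerate results; CI bounds are clamped to
  [−1, 1]; the batch AC path returns NaN for degenerate replicates and
  the power estimator reports their count.
- Report rendering rounds coefficients to 3 decimals and percentages to
  1 decimal; serialization is deterministic for a fixed input and seed.

## Known limitations

- Krippendorff's alpha and average-measure ICC forms are out of scope.
- The inter-observer ICC is assumed to use the same absolute-agreement
  single-measure form as the intra-observer ICC.
- The generator's NA independence means NA-concordance coefficients on
  synthetic data sit near their no-information level given prevalence;
  they exercise the machinery, not a correlated-NA data-generating story.
- Exact replication of closed-form kappa-based sample-size tables is not
  attempted (see the precision-search rationale above).
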