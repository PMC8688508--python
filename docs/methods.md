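# Methods

This note documents the models, procedures and numerical choices behind
`aitia`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

The package targets binary outcome prediction from small tabular clinical
cohorts: one row per surgery, ~20 raw pre-treatment fields (demographics,
blood pressure, lifestyle, FAAM/EILP patient-reported questionnaire
scores, five care-pathway dates, prior-history flags), and a binary label
— return to full deployability within one year (good) versus sustained
downgrade (poor). The regime of interest combines a small sample
(~126 records), marked imbalance (minority fraction ≈ 0.23) and genuine
class overlap: patients whose presentation and outcome do not align.

## Synthetic cohorts

The original clinical cohort is not available, so cohorts are simulated.

**Model.** Each record carries a scalar *severity* latent
`u ~ N(±d/2, 1)` by outcome class, with mean gap `d = 6·(1 − overlap)`.
Every continuous raw field is a noisy reflection of `u`: feature latent
`s·0.6·u + √(1−0.6²)·ε` with field-specific sign, centre and scale (good
outcomes skew younger, taller, lighter, lower blood pressure, higher
questionnaire scores). Because the class signal lives in the single shared
latent rather than accumulating independently across fields, the `overlap`
parameter in [0, 1] moves the cohort smoothly from cleanly separable
(`overlap = 0`) to indistinguishable classes (`overlap = 1`); this is the
one knob the interrogation stage must recover. Pathway dates are an onset
date plus exponential waiting times (months) log-scaled by the severity
latent, so the six derived durations are co-linear by construction —
notably TTT = TTD + wait exactly — mirroring the strong duration
correlations of real referral pathways. Binary history flags are
outcome-dependent Bernoulli draws whose rates converge as overlap → 1.

**Defaults** are the study conditions: 126 records, minority fraction
29/126, 20% missingness in FAAM/EILP (missing completely at random),
no injected outliers. Outlier injection, when requested, multiplies 3–5
numeric fields of a chosen row to 4× beyond the observed range.

**What the generator does not emulate:** the real cohort's joint
distribution beyond marginal ranges and the co-linearity structure,
surgeon effects, informative missingness, or calibrated marginals (the
original descriptive statistics are not public). Passing tests therefore
demonstrate the *machinery* — protocol shape, leakage guards, measure
arithmetic, knob recovery — not clinical performance.

A second generator produces two-class truncated-Gaussian mixtures
(truncation at 4 SD, centre gap `8·(1 − overlap)`) with analytically
known per-point posteriors, used to validate overlap-sensitive code with
closed-form ground truth: supports are disjoint at `overlap = 0` and
coincide at `overlap = 1`.

## Preprocessing

Raw fields are grouped to ordinal/categorical levels, encoded as
consecutive integers from 0 in increasing severity/magnitude order:

- age ≤25 / (25, 30] / >30; height <170 / [170, 180) / ≥180 cm;
  weight <75 / [75, 85) / [85, 95) / ≥95 kg (the boundary between the two
  top classes is taken at 95 kg, keeping bins contiguous);
- BMI by WHO classes (<18.5 / <25 / <30 / ≥30), from weight/(height m)²;
- blood pressure by AHA 2017 categories — systolic <120 / 120–129 /
  130–139 / ≥140; diastolic <80 / 80–89 / ≥90; the overall BP category is
  the worse of the two (Elevated only when systolic 120–129 with
  diastolic <80);
- MAP = (systolic + 2·diastolic)/3 — the standard clinical formula —
  banded <60 / [60, 100) / ≥100;
- smoking Non / Light (<10/day) / Moderate (10–20) / Heavy (>20);
  alcohol ≤14 vs >14 units/week; FAAM and EILP in five 20-point bands;
- job ranks ≥2 collapsed to one level; history flags binarised;
- the six pathway durations (chronicity, TTP, TTD, TTT, TDG, wait time),
  in months at 30.44 days/month, binned at cohort tertiles. Tertile edges
  live in a `BinConfig` so they can be frozen and reused across cohorts.

The result is always exactly 23 feature columns.

**Imputation.** Only FAAM/EILP may be missing. The default (*faithful*)
mode replaces a missing value with the median of the record's outcome
group over the full matrix — reproducing the original study's procedure,
which is knowingly label-leaking. The *hygienic* mode is provided for
leak-free evaluation: medians are computed on training-fold rows only,
and held-out rows receive the training fold's overall median, since their
outcome must be treated as unknown at predict time. Group medians are
rounded to the nearest level so imputed values stay on the declared level
set. Faithful is the default to stay reproducible with the original
procedure.

**Outlier removal.** Each record gets a relative-density score: on
min–max-normalised features, density = 1 / (mean Euclidean distance to
the 10 nearest neighbours), floored at 10⁻¹² so exact duplicates are
well-defined (score 1); the score is the mean neighbour density divided
by the record's own density. Records above Q3 + 1.5·IQR of the scores
(strict inequality) are removed. Scoring runs on the *raw* numeric fields
plus the derived durations, before any grouping: binning saturates
extreme values into terminal bins and would hide exactly the records the
detector exists to catch, and min–max normalisation is only meaningful
where fields have heterogeneous ranges. Pathway tertiles are computed
after removal.

## Cohort statistics and statistically-derived feature sets

Normality is screened per feature with Kolmogorov–Smirnov (against a
normal with sample-estimated mean/SD) and Shapiro–Wilk. Between-outcome
differences use Mann–Whitney U for ordinal features and Pearson
chi-square (no continuity correction, switchable) for binary ones; all
tests two-sided, α = 0.05 by default. The reported Z is the tie-corrected
normal approximation without continuity correction (the form under which
Z values are conventionally reported); the p-value is exact for small
untied samples and asymptotic otherwise. Feature pairs with Spearman
|ρ| > 0.5 are flagged co-linear; constant features yield undefined
correlations and are reported as missing.

Candidate sets are built per alpha in {0.05, 0.01, 0.001}: all features
with p < α, then co-linear conflicts are resolved greedily by dropping
the larger-p member of each violated pair; additional variants (capped at
3 per alpha) flip the keep-choice of one conflicting pair at a time. The
mechanism by which several sets arise per alpha was a genuinely open
design point; this enumeration is the choice made here, and both the cap
and the rule are configuration, not inference.

## Feature selection (TAGA)

The combinatorial selector restricts to the 12 features with the highest
two-class Fisher scores
`F_j = Σ_c n_c (μ_jc − μ_j)² / Σ_c n_c σ²_jc` (denominator floored at
10⁻¹², so a feature constant in both classes scores 0). Fixed-cardinality
λ-subsets then evolve by asexual single-swap mutation under a FIFO tabu
list of the most recently tested swaps; fitness is the mRMR difference
`mean MI(feature; label) − mean pairwise MI(feature; feature)` with
plug-in discrete mutual information on the ordinal levels. Survival is
(μ+λ)-style truncation, so the best fitness is non-decreasing across
generations. Each cardinality λ ∈ {2, …, 10} is run 30 times and the
final set takes the λ most frequently selected features (ties by Fisher
score, then name). GA internals default to population 50, generations
100, tabu size 20 — all configurable; tests and the default pipeline use
smaller settings, which suffice at 12-feature pool sizes.

The expert set is *configuration, never computed*: a clinician-chosen
combination validated to be a subset of the union of the best
statistical and best TAGA sets (the shipped default is height, MAP,
EILP, TTT, TDG, prior surgeries). The orchestration layer falls back to
accepting the configured list verbatim (with a warning) when that union —
on an arbitrary synthetic cohort — does not contain it.

Candidate sets are compared by ranking per-classifier AUC (rank 1 = best,
average ranks on ties); the winner minimises the summed rank, with ties
broken by higher mean AUC and then name.

## Model development and evaluation

The battery comprises logistic regression, linear SVM, KNN, random
forest, XGBoost, bagged SVM and bagged KNN (25 bootstrap estimators
each — the ensembling scheme is this package's documented assumption),
and a small feed-forward network. The default *reduced* battery
(logistic, linear SVM, KNN) keeps the full protocol at desk scale; the
8-model battery is one switch. Hyperparameter grids are deliberately
small and documented in `DEFAULT_GRIDS` (e.g. SVM C ∈ {0.01, 0.1, 1,
10}; KNN k ∈ {3, 5, 7, 9}; forest trees ∈ {100, 300}); the original
study's tuned values are not public, so grids are configuration.

Protocol per repeat: stratified 5-fold outer split; per outer fold, a
stratified 4-fold inner grid search maximising mean validation AUC; the
winner is retrained on all non-test data and evaluated on the held-out
fold. 30 repeats give 150 held-out evaluations per classifier. Fold
assignments are a function of (seed, repeat) only, so all models see
identical partitions. SMOTE (when enabled, the default) balances the
training partition only: each synthetic row is a convex combination of a
minority record and one of its k = 5 minority neighbours on the ordinal
encodings, rounded to the nearest valid level; the neighbour count
shrinks with a warning when the minority is too small, and a singleton
minority is an error. Min–max scaling is fit on the (augmented) training
partition only. Held-out rows are never resampled, rescaled with their
own statistics, or otherwise touched — the evaluator records a checksum
of every test fold, which the test suite compares against the pristine
input matrix.

Metrics: accuracy, sensitivity, specificity from confusion counts at
probability threshold 0.5; AUC by trapezoidal ROC; and FPR/TPR at the
optimal operating point, the ROC threshold where TPR meets 1 − FPR
(realised as the threshold minimising |TPR − (1 − FPR)|, ties toward
higher TPR). Hard-margin classifiers expose a decision score, mapped
through a logistic link; the link is monotone, so ranking-based metrics
are unaffected. Cross-model comparison uses Friedman's test on the
paired 150-length metric vectors, with pairwise Wilcoxon signed-rank
post hocs at a Bonferroni-adjusted threshold 0.05/C(n_models, 2) when
the Friedman test is significant.

## Interrogation

Instance hardness thresholds each classifier's *mean out-of-fold
probability across the 30 repeats* at 0.5 — per-repeat aggregation was an
open point; the aggregated form matches the sweep's use of mean
probabilities and is the choice made here. The four measures:

- **KDN** (k = 5, the convention of the instance-hardness literature;
  configurable): fraction of the k nearest neighbours (Euclidean on
  min–max-scaled encodings, self excluded) with a different label.
  Distance ties — common on coarse ordinal encodings — are broken by
  record index, making neighbour sets deterministic and exactly
  reproducible by brute-force enumeration.
- **DS**: `(|disjunct(x)| − 1)/(max_y |disjunct(y)| − 1)` with disjuncts
  realised as leaves of an unpruned CART tree grown to purity; if every
  leaf is a singleton, DS is 0 everywhere.
- **DCP**: class purity of the covering leaf of a pruned tree (minimum
  leaf size 5). The disjunct-inducing model is unspecified in the
  measures' original presentation; unpruned-to-purity for DS and
  min-leaf-5 for DCP follow the instance-hardness literature's usage.
- **CLD**: `CL(x, t(x)) − max_{c ≠ t(x)} CL(x, c)` with
  `CL(x, c) = Π_i P(x_i | c)` under additive Laplace smoothing (α = 1),
  so unseen levels are well-defined.

Sweeps compute each model's AUC on record subsets thresholded by a
measure, accumulating from easy to hard or shedding the easy end;
threshold grids default to the sorted unique measure values, and points
where one class vanishes are dropped (AUC undefined). Fixed cut-offs are
deliberately not hard-coded: the interesting thresholds are
dataset-derived.

## Orchestration and reproducibility

Stages communicate via files in the output directory, so any stage can be
re-run in isolation; a manifest records the configuration hash, per-stage
seeds and timings, and SHA-256 checksums of every artifact. Identical
configurations reproduce identical checksums (asserted in the test
suite). All randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Problem sizes used by the test and acceptance runs

The shipped checks run the full 5 × 30 protocol on 126-record cohorts
with the reduced battery, the overlap-recovery study on a 5-point overlap
grid × 10 seeds, oracle-equivalence on 50 randomized ≤12-record fixtures,
and the SMOTE contrast at 10 repeats — sizes chosen to exercise every
code path at full protocol fidelity on a single CPU.

## Known limitations

- Generator marginals are schematic, not calibrated to the original
  cohort; dataset-dependent results (specific metric values, specific
  correlation magnitudes) are not reproduction targets.
- Faithful imputation leaks label information by design (it reproduces
  the original procedure); use hygienic mode for unbiased estimates.
- Plug-in mutual information is biased upward at small n; the TAGA
  fitness is a ranking device, not an information estimate.
- The weight-bin boundary and the exact pathway bin edges in the source
  description are ambiguous/unstated; the choices above are documented
  and configurable rather than inferred facts.
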