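# Methods

This note documents the models and procedures implemented in `oaprogress`,
the choices made where the design was genuinely open, and what results on
synthetic cohorts do and do not demonstrate.

## Progression classes

A *period* is an interval of at least 2 years between two visits of one
patient. Its class is computed from raw outcome measurements only:

* **Pain (P)**: with p the WOMAC pain subscale on the 0–100 scale, Δp its
  annualized change and p_s, p_e its start/end values, the criterion is
  ((Δp ≥ 5 ∩ p_e ≥ 40) ∪ (Δp ≥ 10 ∩ p_e ≥ 35)) ∪ (p_s ≥ 40 ∩ p_e ≥ 40).
  All comparisons are inclusive, matching the "at least" phrasing of the
  rules. A helper rescales raw 0–20 subscale scores by ×5 when a cohort
  reports them unnormalized.
* **Structure (S)**: annualized loss of minimum joint-space width (JSW) of
  at least 0.3 mm/year, also inclusive.
* **P+S** if both, **N** if neither.

Per-knee resolution: structural quantities come from the knee with greater
narrowing; pain at each endpoint is the maximum over knees reporting at that
timepoint. Two readings were open:

* *Per-timepoint maximum vs single worst knee for pain* — the per-timepoint
  maximum is implemented (the start and end pain may come from different
  knees). The pain and structure criteria may likewise use different knees
  within one period; the two criteria are treated as independent.
* *Knee ties on narrowing rate* — broken towards the smaller end-of-period
  JSW (the more affected end state); deterministic.

Periods whose required raw measurements are missing are excluded
(`unmeasurable`), never imputed. Periods ending at or after the earliest
knee replacement of either knee are excluded (`post_replacement`): outcome
measurements at or after replacement no longer describe the native joint.

## Synthetic cohorts

The target cohorts are controlled-access, so the generator provides the test
bed. Its defaults mimic their published shape: visit grids {0,2,5,8} or
{0,1,2,3,4,6,8} years, class proportions (0.63, 0.12, 0.20, 0.05) over
(N, P, S, P+S), per-knee pain and JSW outcomes, KL grades, ACR-relevant
covariates (age, morning stiffness, crepitus, osteophytes), a small
knee-replacement rate (3%), and a missingness knob (the studied cohorts
report 34–59% missing covariate cells).

Each patient draws one latent class; outcome trajectories are sampled
*backwards from the class* so that **every** enumerable ≥2-year window of
that patient satisfies (or violates) both criteria as the class requires:

* JSW is linear per knee; structural progressors narrow at 0.35–0.5 mm/year
  (every window's rate equals the slope), non-progressors at 0–0.1 mm/year.
  The margin around the 0.3 threshold makes recoverability exact.
* Pain-positive patients are either *sustained* (a random walk confined to
  [43, 95], satisfying the sustained clause on every window) or *rising*
  (slope 5.5–9 points/year with an intercept keeping every valid window end
  ≥ 41 and the trajectory ≤ 98).
* Pain-negative patients are either *low* (i.i.d. values in [0, 30], below
  every end-pain threshold) or *improvers* (substantial baseline pain
  fading below 34 by the earliest valid window end) — the improvers give the
  conventional criteria non-progressors to select, as observed in real
  screening.
* The second knee is generated strictly less affected, so the most-affected
  resolution always lands on the driver knee.

Every draw is verified against the labeling module over all windows and
redrawn on failure (capped at 1000 draws); the margins make rejection rare.
This replaces free rejection sampling over trajectory space with sampling
from pre-constrained regions plus verification — it guarantees the label
recoverability invariant while keeping generation a pure function of the
seed (sub-streams for trajectories, features, clinical covariates and
replacements are spawned from one master seed).

Informative covariates are class-conditional: continuous features are shifted
per class by `signal_strength` times a fixed random offset pattern;
categorical features tilt one preferred level per class with softmax weight
`exp(signal_strength)`. Noise features are class-independent. Knee
replacement uses an exponential waiting time (scale = half the follow-up)
snapped up to the visit grid; it truncates subsequent outcome measurements.

**What the generator does not emulate**: clinically calibrated trajectory
shapes, informative (MNAR) missingness, site effects, and within-patient
class changes over time — a patient's class is constant, so all periods of a
patient share the label and near-identical covariates. Because stratified CV
splits by period (as the study design does), overlapping periods of one
patient land in both partitions and classifiers can partially memorize
patients; synthetic scores therefore run much higher than is achievable on
real cohorts. Tests that must be sensitive to feature signal (signal
monotonicity, RFE, the XOR depth-recovery check) use one period per patient
or purpose-built feature matrices instead.

## Preprocessing

Fixed order: enumerate periods → carry-forward/defaults → filter → infer
kinds → (inside every CV fold) impute → one-hot encode → optionally scale.

* Period policy: all ordered visit pairs ≥ 2 years apart (maximizing
  instances); a consecutive-pairs alternative is available. Features come
  from the period's *start* visit only — end-of-period covariates would leak
  the outcome.
* Filters: identifier attributes always dropped; attributes missing in
  strictly more than 50% of instances; instances missing strictly more than
  40% of surviving attributes; attributes with a single non-null value.
  Attributes are filtered before periods, so instance missingness is
  computed over surviving attributes. Note that dropping constants *after*
  the period filter means a second application can, in contrived cases,
  remove further rows; on realistic tables filtering is idempotent.
* Kind inference: unlabeled attributes with ≤ 10 distinct non-null values
  are categorical, others continuous; explicit metadata always wins.
* Imputation: training-partition mode (categorical/ordinal; ties to the
  smallest value) or mean (continuous). Encoding: one dummy per level for
  >2-level categoricals, a single 0/1 column for binary ones, numeric ranks
  for ordinals; unseen levels at apply time encode as all-zeros rather than
  erroring. Scaling (for scale-sensitive learners only) maps training
  bounds to [0, 1]; constant columns to 0; held-out values may fall outside.
  All fitted state is serializable to JSON for exact reapplication.

## Models

Four strategies share one fit/predict contract returning (class, p(P),
p(S)): a single 4-class learner, one-vs-rest, multi-label, and the *duo
classifier* — two independent binary learners for the P and S labels whose
joint vote maps to the four classes. Decisions taken:

* Class weights use the balanced convention w_c = n/(k·n_c); the source
  distribution is the full dataset by default (training fold optional). For
  tree learners any positive rescaling of "inversely proportional" weights
  is equivalent. Duo sub-models weight by their own binary label
  distribution by default; deriving binary weights from the 4-class
  distribution is available behind `duo_weight_basis`.
* The duo class decision uses each sub-forest's native majority vote, not a
  0.5 probability cut (for forests these coincide; the probabilities are
  reported independently). Both sub-models share one configuration.
* Non-duo strategies derive p(P) = Pr(P) + Pr(P+S) and p(S) = Pr(S) +
  Pr(P+S); the one-vs-rest scores are normalized into a distribution first.
* Base learners are pluggable presets (random forest default; logistic
  regression in one-vs-rest form, multinomial logistic regression, kNN,
  linear and RBF SVC); kNN has no class-weight support and silently trains
  unweighted.

## Evaluation

* **Weighted F1**: per-class F1 weighted by true-class frequency, over
  classes present in the truths; implemented from confusion counts via
  F1_c = 2·TP_c/(support_c + predicted_c) for speed inside BBC-CV. An
  independent implementation (and scikit-learn's) serves as test oracle.
* **Repeated stratified CV**: 10 folds, repeated with different partitions,
  each model retrained under several seeds held constant across folds and
  repeats; out-of-sample predictions are pooled into one score per
  (repeat, seed, configuration). The typical score is the median over
  repeats of the median over seeds. The study-scale plan (10 repeats × 25
  seeds) is configurable; the desk plan (3 × 5) runs in minutes and is used
  throughout the tests, with sizes stated per test.
* **Balanced protocol**: the cost-sensitive arm trains on full imbalanced
  training folds; the balanced arm down-samples each training fold to equal
  class counts (11 sampling seeds), both scored on bit-identical test folds.
* **Grid search**: exhaustive over 6 tree counts × 7 depths × 2 criteria
  (84 configurations); the winner has the highest median-of-medians, ties
  broken by lowest median absolute deviation, then lower depth, fewer
  trees, gini before entropy.
* **BBC-CV with repeats** (B = 1000): bootstrap over instances; the
  configuration winning on the bootstrap sample (using all repeats'
  predictions, concatenated by default — per-run averaging is available via
  `aggregation="mean_over_runs"`) is scored on out-of-bootstrap instances;
  the estimate is the mean out-of-bootstrap score with a percentile
  interval. Empty out-of-bootstrap draws are redrawn and counted.
* **RFE**: backward elimination on the outer training fold with an inner
  3-fold loop; importance is the learner's native feature importance
  averaged over inner folds (sub-models averaged for multi-model
  strategies); the selected subset maximizes the inner score, ties towards
  fewer features. Degenerate folds (a class missing from a training
  partition) are skipped with a warning rather than crashing.

## Selection scenarios

* Conventional: per knee, knee pain AND (age > 50 OR stiffness < 30 min OR
  crepitus OR osteophytes) AND KL grade in [1, 3] AND WOMAC pain ≥ 40; a
  patient qualifies if either knee satisfies all clauses *on that knee*
  (age/stiffness are patient-level). Missing components fail their clause —
  conservative inclusion.
* ML-L: all instances predicted out of class N, taken from "the median
  model" — the (repeat, seed) run whose pooled score is closest to the
  median-of-medians, ties to the lowest seed.
* ML-P: three descending rankings by p(P)+p(S), p(S), p(P); each fills a
  third of the count-matched target, remainder to earlier groups, ranking
  ties broken by instance id. An instance already taken by an earlier group
  is skipped so exactly n distinct instances return; the alternative reading
  (duplicates consume quota) is available behind `duplicate_policy`.

## Numerical and scale choices

Seeds everywhere derive from explicit master seeds through
`numpy.random.SeedSequence` and stay below 2^31. The acceptance script uses
cohorts of 80–1400 patients (periods from ~300 to ~23000 depending on the
quantity), forests of 25–100 trees, and desk-scale CV plans; each reported
quantity states the problem size it was computed at. The down-sampling
demonstrations use cohorts large enough that the rarest class (~5% of
periods, clustered within patients) exceeds the per-class draw with wide
margin at any seed.

## Known limitations

* Synthetic trajectories are piecewise-linear with margin-separated rates;
  real pain fluctuates around the thresholds, so real-world labeling is
  noisier than the exact recoverability shown here.
* Period-level CV (as in the study design) lets information flow between
  overlapping periods of one patient; grouped CV would estimate
  per-patient generalization but is out of scope here.
* SHAP-based interpretation and per-sub-model tuning of the duo classifier
  are not implemented; RFE uses native importances.
* AUC/MCC are deliberately not used for model selection; weighted F1 is the
  single selection measure.
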