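# Methods

`radcog` implements a subject-level analysis of rodent attentional
set-shifting (ATSET) performance under simulated galactic-cosmic-ray
exposure: derive behavioral scores from trial logs, fix impairment
thresholds from the non-irradiated (sham) cohort, label every subject, and
predict post-irradiation impairment from prescreen scores plus dose with
class-weighted leave-one-out classification. This note records the models,
the defaults and why, and the design choices made where the procedure was
genuinely open.

## The behavioral assay and its scores

A stage of the ATSET gives a rat up to 30 digging trials per day, at most
two days; the stage is passed on a run of 6 consecutive correct attempts.
The prescreen phase administers four stages (SD, CD, CDR, IDS); the
post-irradiation phase administers seven (SD, CD, CDR, IDS, IDR, EDS, EDR).
Three scores summarise a stage, all lower-is-better:

* **ATRC** (attempts to reach criterion): day-1 attempts if the criterion
  is reached on day 1, otherwise 30 + day-2 attempts. Integer, minimum 6;
  a day-2 pass therefore always scores ≥ 31.
* **FR** (failure ratio): incorrect / total attempts, pooled over both
  days. Note one narrative illustration in the source literature assigns
  the 24-attempt, 3-error sequence an FR of 1/3; the printed definition
  gives 3/24 = 0.125 and this implementation follows the definition.
* **MCL** (mean correct latency): mean time of successful attempts, in
  seconds; if day 1 was failed, only day-2 successes count. Absent (never
  zero) when no qualifying success exists.

A rat that fails both days keeps defined scores (ATRC = 30 + day-2
attempts, i.e. 60 for two full failed days) and carries a
`criterion_unmet` flag so downstream analyses can exclude it; FR may reach
exactly 1 in the all-fail case. Latencies of incorrect attempts are
ignored throughout.

## Step 1 — impairment thresholds from the sham empirical CDF

The sham cohort defines normal performance. For a stage and score type,
the threshold is placed so that at least a fraction `level` (default 0.95)
of sham subjects score strictly below it, on the score's natural grid
(integers for ATRC, observed values for MCL); a subject is **impaired iff
its score ≥ threshold**.

The two natural phrasings of a 95% rule — "the score at or below which 95%
pass" and "at or above the threshold is impaired" — contradict each other
at the threshold value itself. The default `tie_rule="strict_below"`
resolves the tie so that at most 5% of sham are ever labeled impaired,
which matches the "≥ threshold ⇒ impaired" labeling contract; the
inclusive reading is available as `tie_rule="at_or_below"`. FR is computed
but never used for thresholding (two very different performances can share
an FR); MCL thresholding is supported but the default pipeline labels on
ATRC only.

## Step 2 — class-weighted LOOCV classification

Features are the dose (cGy) and the four prescreen ATRC scores; subjects
missing any required prescreen stage or the post stage under prediction
are excluded (exclusions counted by reason). Labels come from Step 1.
Cross-validation is leave-one-out with N folds — each subject tested once
on a model trained on the other N−1. (Some descriptions of LOOCV say the
process repeats "N−1 times"; standard practice, used here, is N folds.)
Class weights w_c = N/(2·N_c) are recomputed on every training fold.
Out-of-fold scores are pooled into a single ranking for the ROC and PR
curves — the only stable choice when each fold tests one subject.

Three classifiers are implemented from first principles:

* **Gaussian naive Bayes** — per-class, per-feature Gaussian likelihoods
  with a variance floor of 1e-9 × the largest feature variance; posteriors
  computed in log space with log-sum-exp. Priors are uniform (0.5, 0.5)
  regardless of class frequencies: the uniform prior *is* the balancing
  mechanism for this model, so no extra likelihood weighting is applied.
  It operates on raw features (the model is scale-equivariant).
* **RBF-kernel SVM** — soft-margin dual solved by sequential minimal
  optimization with first-order maximal-violating-pair selection;
  deterministic (ties broken by lowest index), stopping at KKT gap ≤ 1e-3.
  Per-class box constraints C_c = C · w_c fold the class weighting into
  the penalty. Defaults C = 1, γ = 1/(n_features · feature variance).
  Decision values are squashed through a logistic for reporting, which is
  monotone (ROC/PR unchanged) and maps the geometric sign rule to the 0.5
  cutoff.
* **Feed-forward network** — fixed architecture inputs → 16 → 8 → 1, ReLU
  hidden activations, sigmoid output; class-weighted binary cross-entropy
  computed on the logit scale; full-batch gradient descent, 300 epochs at
  step 0.5, small symmetric uniform initialization from a seed (bit
  reproducible). These training choices are the package's own: the loss
  decreases monotonically at this step size on standardized features, and
  full-batch descent keeps runs deterministic and order-independent.

Features are standardized with training-fold mean/sd for the SVM and the
network (needed for a sensible RBF width and gradient conditioning); the
naive Bayes uses raw features. Each ion is analyzed in its own model run
against sham; no cross-ion pooling.

### Metrics

Accuracy, precision, recall, F1 and the Matthews correlation coefficient
from confusion counts at a score cutoff (default 0.5; the cutoff that
produced published hard metrics is generally unknowable, so it is
configurable). Zero-denominator conventions: precision/recall/F1 are 0
when undefined; MCC is 0 when any confusion-matrix marginal vanishes (the
random-guess value). ROC AUC uses the trapezoidal rule over all distinct
cutoffs, which equals pairwise concordance with ties counted 1/2. PR AUC
uses step-wise summation over achievable operating points — no linear
interpolation, which is known to be optimistic for PR curves — so
cross-checks against other software must use the matching variant. The PR
no-skill baseline is the positive-class fraction. Uncertainty is by
nonparametric bootstrap only.

## The synthetic cohort generator

The real behavioral dataset is access-restricted, so the package ships a
generator whose default parameters *are* the study conditions for every
test. Per subject with latent ability a ~ N(μ, σ_a):

    P(correct at attempt t) = logistic(a + λ·t),   t = 0, 1, 2, …

with t counting attempts cumulatively across a stage's two days (learning
carries over the overnight rest). Correct-attempt latencies are lognormal.
Post-irradiation ability is a − d(ion, stage, dose) + s, where d is a
per-(ion, stage) dose coefficient (with per-dose overrides available for
non-monotone responses) and s ~ N(0, σ_r) is a subject-level retest /
radiosensitivity term drawn once per subject, so equal-prescreen subjects
can receive different outcomes. A subject failing two post stages is
dropped from later stages. The habituation stage is treated as always
passed and never simulated. Every subject draws from a substream keyed on
(seed, subject index), so growing a design never reshuffles existing
subjects.

Defaults: μ = 1.6, σ_a = 0.3, λ = 0.12, σ_r = 0.8, latencies
lognormal(ln 10, 0.4); susceptibilities (per cGy) Fe: 0.140 (SD) / 0.135
(CD), Si: 0.110 (SD), He: 0 (SD) / 0.020 (CD), O: 0.060, Ti: 0.070,
0.050 for unlisted (ion, stage) pairs, and a non-monotone Si CD response
via per-dose total decrements {1: 0.15, 5: 0.05, 10: 0.85, 15: 1.20}.
These were fixed once, by calibration against the qualitative structure
the analysis assumes, and are not tuned per experiment:

* the sham SD/CD threshold lands near the high teens with 4–6% of a large
  sham cohort labeled impaired under the 95% rule;
* percent impaired rises monotonically with dose for Fe (SD and CD) and
  Si (SD), stays flat for He (SD), and dips at the middle dose for Si
  (CD), reaching roughly 25–30% for 10 cGy of Fe;
* the prescreen–post ability correlation is deliberately modest
  (σ_a ≪ σ_r): with a strong correlation, prescreen scores alone predict
  tail membership and even a no-effect ion becomes "predictable", which
  contradicts the observed effect-vs-null ion contrast. With the default
  balance, the dose term carries most of the discriminative signal; the
  null ion's pooled-LOOCV AUC is at chance while the effect ion's is
  ≈ 0.65–0.70.

What the generator does **not** emulate: physiological covariates, stage
difficulty differences, within-day fatigue, mixed-ion exposure, or
attrition before the post-irradiation phase (the shipped arm table's
sample sizes are taken as the post-SD counts). Under the default learning
rate, a full day-2 failure is vanishingly rare, so stage dropout
essentially never occurs in default cohorts — tests of the dropout
mechanism use a flatter learning curve. Passing tests therefore
demonstrate the pipeline's statistical behavior under this model, not
fidelity to any particular animal dataset.

## Numerical and degenerate-input choices

* Trial success probabilities are clamped to (0, 1), so infinite abilities
  are valid limit cases (pass in exactly 6; fail all 60).
* The empirical CDF is right-continuous; the threshold scan uses a strict
  1e-12 slack when comparing mass against `level` to absorb float division.
* SMO handles a degenerate (duplicate-point) working pair by moving to the
  box end that maximizes the exact dual-objective change; the dual
  objective is non-decreasing across iterations.
* Mann–Whitney comparisons (descriptive, per-comparison, no multiplicity
  correction) delegate to SciPy: exact null for small tie-free samples,
  otherwise the normal approximation with tie and continuity corrections;
  two identical pooled samples return p = 1 by convention. The identity
  U/(n_A·n_B) = ROC AUC (group as label) ties this module to the
  evaluation code and is tested.
* Every artifact embeds the configuration hash and seed; two runs with the
  same configuration are byte-identical.

## Problem sizes used by the shipped experiments

The acceptance script analyzes the default 432-subject design and a
parameter-recovery experiment of five replicate two-arm cohorts (sham +
10 cGy, 150 subjects/arm) per ion; the test suite's recovery check uses
twenty replicates and a two-arm design per ion, with the mean AUC's
percentile-bootstrap CI across replicates deciding above-chance vs
at-chance. Monte-Carlo oracle checks use 3×10⁴ simulated stages against an
exact dynamic-programming streak probability, and 10⁴-subject sham cohorts
for threshold calibration.

## Known limitations

* The generator's latent-ability model is one of many that reproduce the
  qualitative structure; absolute metric values on synthetic cohorts are
  not comparable to values computed on the restricted experimental data.
* The SVM reports no calibrated probabilities; its 0.5-cutoff hard metrics
  are the geometric sign rule, and only ranking metrics should be compared
  across classifiers.
* LOOCV metrics on small, highly imbalanced samples have large variance;
  the recovery experiment averages over replicate cohorts for this reason.
* Exact reproduction of published metric tables is out of scope: the
  underlying dataset is restricted and the published training schedules
  are underdetermined.
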