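# Methods

## Model and guarantee

The package implements the inductive (split) variant of conformal
prediction for classification, in its Mondrian, class-conditional form.
A fixed underlying classifier supplies a probability vector
p̂(· | x) over a label set Y. A calibration set {(x_i, y_i)}, held out
from classifier training, yields nonconformity scores
α_i = 1 − p̂(y_i | x_i), stored per true class. For a new example x and
candidate label y, with α_new = 1 − p̂(y | x) and n_y calibration scores
in class y:

    non-smoothed   p(y) = ( #{α_i ≥ α_new} + 1 ) / (n_y + 1)
    smoothed       p(y) = ( #{α_i > α_new} + τ·(#{α_i = α_new} + 1) ) / (n_y + 1),
                   τ ~ U(0,1) per (example, label), seeded

The prediction region is {y : p(y) > 1 − c(y)} with per-class confidence
c(y). If calibration and test examples of class y are exchangeable, the
probability that the true label is excluded is at most ε(y) = 1 − c(y)
(non-smoothed, conservative) and exactly ε(y) (smoothed). Stratifying by
the true class makes the bound hold within each class, which matters
under the heavy imbalance of biopsy grading (the rarest grade is ~4% of
examples); an unstratified predictor would let rare-class errors exceed
ε while the average stays below it.

Conventions fixed here, where the construction admits variants:

* **Nonconformity direction.** One minus the predicted probability,
  larger = less conforming. Using the probability itself with the
  opposite comparison direction yields identical regions; one convention
  is fixed and documented.
* **Inclusion rule.** Strict inequality p > 1 − c. This keeps empty
  regions reachable at high ε.
* **Default p-value.** Non-smoothed, because it is deterministic and
  reproducible; smoothed p-values are used for distributional
  diagnostics (uniformity, per-class error tracking), where exactness
  matters.
* **Ties.** Handled by the counting definitions above; no midrank
  heuristics.
* **Small strata.** With n scores the smallest attainable p-value is
  1/(n+1), so a stratum with (n+1) < 1/ε can never exclude its label; a
  warning is emitted both at calibration time (below `min_per_class`,
  default 25) and at prediction time when a requested ε is unreachable.

## Splitting

`split_train_calibration` reserves 10% of the labeled data for
calibration by default. When a subject identifier is present the split
operates on whole subjects (shuffled, accumulated until the calibration
row count reaches the target), because biopsies from one man are not
exchangeable with each other; the achieved fraction is then within one
subject of the target. Whether to additionally stratify by class is left
to the caller; the default split is by subject only.

## Synthetic score generator

No trained classifier ships with the package, so the generator produces
probability vectors with the statistical structure the analysis assumes.

* **calibrated** (default): v ~ Dirichlet(d·K·π) where d is the
  discriminability, K the number of classes and π the prevalence vector
  (the symmetric Dirichlet(d) when π is uniform); the true label is then
  drawn *from* v. Scores are perfectly calibrated by construction, rows
  are i.i.d. (hence exchangeable across any split), and the marginal
  class frequencies equal π. This regime is the testbed for validity:
  conformal coverage needs only exchangeability, not score quality.
* **class_conditional**: the label comes first (categorical π), then
  v ~ Dirichlet(1,…,1 with d added to the true class). One parameter
  controls difficulty; scores are deliberately *not* calibrated,
  mimicking an imperfect classifier for evaluation-surface demos.

Default prevalences for the six-class grading task are the biopsy-grade
frequencies 3724/1530/539/263/469/426 (benign through ISUP 5, n = 6951);
raw counts are accepted and normalized. Default discriminability is 1.0
(uniform prior over the simplex in the binary calibrated regime).

Shift scenarios model deployment changes:

* **temperature** T: v ← v^(1/T), renormalized. T = 1 is an exact
  identity; T → ∞ flattens scores. Stands in for a systematic score
  distortion such as a scanner or laboratory change.
* **contamination** f: a seeded random fraction f of rows is replaced by
  draws from a symmetric Dirichlet with concentration 200 — nearly
  uniform vectors, but with enough noise that exact nonconformity ties
  stay rare and tie-handling does not dominate downstream behavior.
  Stands in for atypical tissue resembling no training class.
* **prevalence_shift**: rows resampled (with replacement, within class)
  to a target class distribution.

What the generator does *not* emulate: real classifier scores carry
correlation structure from patch aggregation and ensembling, calibration
error that varies with the input, and label noise from interobserver
variability. Passing validity tests on this generator demonstrates the
conformal machinery is correct under its stated assumption
(exchangeability), not that any particular real classifier satisfies
that assumption — detecting the latter's failure is exactly what the
drift module is for.

## Evaluation definitions

Each (region, truth) pair falls in exactly one category: **empty**
(|R| = 0), **error** (|R| ≥ 1, truth ∉ R), **correct single**
(R = {truth}), **correct multiple** (|R| ≥ 2, truth ∈ R). Efficiency is
the fraction of correct singles. Two error notions are kept distinct:
the tally's "error" excludes empty regions (so categories partition n),
whereas the calibration curve counts every excluded truth — empty
regions included — because that is the quantity the guarantee bounds.
Percentages are reported rounded to whole percent with raw counts
alongside.

The calibration curve evaluates, on a uniform ε grid (default 1001
points), the fraction of true-label p-values ≤ ε; it is non-decreasing,
starts at 0 (p-values are strictly positive) and is compared against the
diagonal.

Panel coverage counts individual rater votes (one per rater per
example) whose label lies in that example's region, divided by all
votes; votes for a label no rater panel member assigned truth-status to
are treated like any other vote.

The human-in-the-loop experiment is an explicitly synthetic stand-in:
for binary detection, every flagged example (empty or multiple region)
has its score replaced by the truth-indicating extreme (1 or 0) with
probability `expert_accuracy`, else the opposite extreme, seeded. AUC is
computed by the rank-based (Mann–Whitney) formulation with midrank tie
handling via scikit-learn.

## Drift detection and power

The drift test KS-compares pooled calibration nonconformity scores with
deployment scores, in one of two recorded modes: `labeled` (scores at
the true label) or `predicted_label` (scores at the argmax label, for
monitoring without ground truth). The two-sided p-value uses the exact
null distribution when both samples have ≤ 100 observations, the
asymptotic Kolmogorov distribution otherwise; the method used is
recorded in the result. Significance defaults to the two-sided 5% level.

The power curve subsamples n rows without replacement from a shifted
pool (n on a strictly increasing grid), runs the drift test per
subsample, and estimates power as the rejection fraction over `n_reps`
repetitions; `n_required` is the smallest grid n reaching the power
threshold (default 0.80, an explicit parameter since no canonical value
exists). One seed governs the whole curve.

## Numerical and reproducibility choices

* p-values are computed by binary search on the sorted per-class score
  arrays; the brute-force counting definition is kept as a test oracle
  and the two are asserted equal (exactly, and to 1e-12 for smoothed
  values sharing tie draws).
* All randomness flows through `numpy.random.default_rng` seeds. The
  pipeline derives per-stage seeds by hashing the master seed with a
  stable stage name (blake2s, reduced below 2^31), so adding a stage
  never perturbs existing streams; two runs with the same config and
  master seed produce SHA-256-identical artifacts.
* Score tables are CSV/TSV with probabilities at 12 significant digits;
  vectors whose sum is within 1e-6 of 1 are renormalized with a logged
  warning, larger deviations are rejected with the row number.
* Argmax point predictions break ties toward the first label in label-set
  order, which is recorded in the label set itself.

## Experiment sizing

The canned experiments (`conformalqc.experiments`) fix these problem
sizes:

* Marginal validity: 5,500 calibration scores per class — ε(n+1) = 5.501
  at ε = 0.001 is non-integer, so the non-smoothed error rate is
  strictly conservative (exactly 5/5501 ≈ 0.091% in expectation) —
  100,000 test rows per seed, 20 seeds pooled. Balanced strata are
  obtained by truncating each class of an i.i.d. stream to its first
  5,500 rows, which preserves exchangeability with the test stream.
* Shift detection: calibration n = 1,000; test n = 449 at T = 2;
  50 seeds; the median KS p-value and the rejection rate are reported.
* Per-class validity and uniformity experiments keep every calibration
  stratum roughly an order of magnitude larger than its test stratum.
  All test examples share one calibration set, so observed error rates
  fluctuate on the calibration-stratum scale as well as the test scale;
  making calibration strata much larger leaves test-side binomial noise
  — the scale the three-sigma comparison bands refer to — dominant.

## Known limitations

* Transductive/online conformal prediction, regression conformal
  prediction, and nonconformity measures built from predictor-variable
  distributions are out of scope.
* The KS drift test compares pooled (not per-class) score
  distributions; a shift confined to a rare class is diluted. Both drift
  modes are interpretations of "the distribution of the predictions";
  the mode is always recorded so results are unambiguous.
* The generator's shift magnitudes are abstract dials, not measurements
  of any real scanner or laboratory difference; reported detection
  sample sizes apply to the synthetic conditions stated, not to any
  particular deployment.
* Exact KS p-values are limited to small samples for speed; at the
  10^2–10^3 sizes used here the asymptotic approximation is adequate and
  the boundary is recorded.
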