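# Methods

## The problem

Preoperative staging of endometrial carcinoma is a binary risk question:
will a patient clinically judged early-stage turn out, after surgery, to
have extrauterine disease (FIGO stage > I)?  The covariates available
before surgery are heterogeneous — two right-skewed serum biomarkers
(HE4 in pmol/L, CA125 in U/mL), demographics (age, BMI, parity),
binary clinical history (menopause, contraception, HRT, hypertension),
an ordered biopsy grading, and the clinician's own early/advanced call —
with covariate-specific missingness.  A regression tree handles this
mixture natively and yields a flow-chart clinicians can act on, but a
single tree is notoriously unstable.  This package implements the
representative-regression-tree (RERT) remedy: grow an ensemble of
CV-pruned trees on stratified bootstrap samples and return the single
best tree by AUC as the deliverable model, with an honest nested
cross-validation estimate of how well that *procedure* predicts.

## Regression trees on a binary outcome

Trees are CART regression trees, not classification trees.  Node
impurity is the squared-error deviance

    I(t) = sum_i (y_i - ybar_t)^2 = n_t * p_t * (1 - p_t),

where `p_t` is the fraction of positives in node `t`, and every leaf
predicts `yhat = n_pos / n` exactly — a relative frequency, readable as
an event probability.  Split search maximizes the impurity decrease
`I(t) - I(left) - I(right)` over all covariates, with thresholds at
midpoints between consecutive distinct observed values.  Ordered
categoricals split as numeric on their level index; nominal categoricals
are searched by sorting levels by within-level outcome mean, which is
exact for squared error.  Ties resolve deterministically: the covariate
earlier in schema order, then the smaller threshold.

Missing values are handled structurally, not by imputation: splits are
scored on observed values only, and rows missing the split covariate
follow the majority of the observed rows, with the direction frozen into
the fitted split rule.  Full surrogate-split machinery is deliberately
out of scope; the majority rule is deterministic and testable, and the
missingness in the data this emulates is modest for most covariates.

Growing stops at `min_split = 20` members, `min_leaf = 7` per child,
`max_depth = 30`, and a complexity floor `cp = 0.01` (a split must
reduce impurity by at least `cp` times the root impurity).  These are
the conventional rpart-style defaults for cohorts of a few hundred
patients; only the fold count `v = 10` is prescribed by the procedure
itself.

## Pruning and subtree selection

Cost-complexity pruning follows the weakest-link construction: collapse
the internal node minimizing

    g(t) = (I(t) - sum of subtree leaf impurities) / (leaves - 1)

repeatedly, yielding a nested sequence of subtrees indexed by strictly
increasing alphas.  The operating subtree is chosen by v-fold
cross-validation (outcome-stratified folds, seeded): each fold regrows a
tree on the training part, prunes it at the geometric means of
consecutive alphas, and scores the held-out rows by squared error.  Ties
in CV error go to the smaller subtree.  Fold assignment continues
round-robin across outcome classes, so `v = n` degenerates cleanly to
leave-one-out.

## Random-forest screening (step i)

The screening step grows a forest of unpruned regression trees
(default 10,000; bootstrap samples, `mtry = max(1, p // 3)` covariates
re-sampled at every split, `min_leaf = 5`) and ranks covariates by Total
Decrease in Node Impurity: the mean over trees of the summed impurity
decreases of every split on the covariate, rescaled so the top covariate
is 100.  Within any single tree the per-covariate decreases telescope
exactly to root impurity minus leaf impurities, which the tests assert.
Covariates with relative importance of at least 60 are reported as the
drivers.  The forest bootstrap is unstratified; stratification belongs
to the representative-tree step only.  A permutation-importance utility
is included as a cross-check but TDNI is the headline metric.

## The representative tree (step ii)

For `b = 1..B` (default 1000):

1. draw a bootstrap sample stratified by histotype — each stratum of
   size `n_s` contributes exactly `n_s` rows drawn with replacement;
2. grow and CV-prune a tree on the sample;
3. score the tree by the AUC of its predictions on the full original
   cohort.

The representative tree is the AUC argmax, ties broken by fewer leaves
(parsimony), then lower replicate index.  A bootstrap sample that loses
an outcome class is redrawn under an incremented retry sub-seed, so the
ensemble always has exactly B members.  Sub-seeds derive from
`(seed, stage, b, retry)` via numpy's `SeedSequence`, making candidate b
identical whatever B is.

### Apparent versus honest performance

`selection_auc` — the winning candidate's full-cohort AUC — is an
apparent number: it is maximized over B replicates of a tree trained on
a resample of the same data, and on pure-noise data it averages well
above 0.5.  The honest figure reruns the *entire* B-candidate selection
inside each fold of an outcome-stratified cross-validation (default 10
folds) and scores each held-out fold with that fold's representative;
the resulting out-of-fold scores give `nested_cv_auc` and feed every
reported operating-point metric.  Both numbers are exposed side by side
because conflating them is exactly the bias the nested evaluation
exists to correct; the test suite demonstrates the gap on pure-noise
cohorts (nested mean near 0.5, apparent mean far above it).

## Evaluation machinery

The ROC curve is built from sorted distinct scores; its trapezoid area
equals the tie-corrected Mann-Whitney statistic (mean over
positive/negative pairs of `1[pos > neg] + 1/2 * 1[pos == neg]`), and the
tests require agreement to 1e-12.  The operating threshold maximizes
Youden's J = sensitivity + specificity − 1 over midpoints between
consecutive distinct scores (with infinite sentinels); ties take the
smallest threshold, favoring sensitivity.  Predictions are positive at
`score >= threshold`.  Confusion metrics with a zero denominator are
reported as NaN with an explicit flag, never silently.

Paired AUCs are compared two ways: DeLong's test via placement values
computed from midranks (the covariance uses ddof = 1; the variance
matches an O(n^2) placement oracle to 1e-10 in tests), and a paired
bootstrap stratified by label with a normal approximation to the
resampled AUC difference.  Association tests are the field's standard
ones — Wilcoxon-Mann-Whitney (exact enumeration when both groups have at
most 8 observations and no ties, tie-corrected normal approximation
otherwise), Kruskal-Wallis beyond two groups, Pearson chi-squared
without continuity correction for two categoricals — delegated to
scipy.  The logistic baseline is a main-effects statsmodels GLM on
complete cases; listwise-deletion counts are reported, and
quasi-separation is detected from pinned fitted probabilities and
flagged.  All p-values are two-sided and uncorrected.

## The synthetic cohort generator

The generator emulates the *structure* of the study cohort, which is not
publicly deposited: 11 covariates, n = 293, ~33.8% outcome prevalence,
histotype split 254:39.  Biomarkers are bivariate log-normal via a
Gaussian copula (HE4 median 77 pmol/L, log-sigma 0.83; CA125 median
17.2 U/mL, log-sigma 1.31; log-scale correlation 0.49), matched to the
published medians and upper tails.  The remaining marginals reproduce
the published category frequencies; missingness is applied completely
at random at the published per-covariate rates (e.g. contraception
87/293).  MCAR is a deliberate simplification: no missingness mechanism
is documented for the original data, and MCAR keeps recovery tests
unconfounded.

The outcome comes from a planted threshold-interaction tree mirroring
the published flow-chart: root on HE4 at 78, then clinical stage, BMI at
31.5, and HE4 again at 135, with leaf probabilities {0.07, 0.95, 0.04,
0.90} taken from the printed leaf values.  The one interior leaf the
flow-chart does not print (78 <= HE4 < 135, early stage, BMI < 31.5) is
set to 0.475, calibrated analytically against the default marginals so
the expected prevalence equals 99/293.  The generator reproduces
marginal shapes and the planted interaction; it does not attempt the
cohort's full conditional structure (e.g. the HE4-age association), so
passing recovery tests show the algorithms work on data of this shape,
not that the original cohort's numbers are reproduced.

### The two-threshold recovery fixture

The fixture for parameter-recovery simulations plants the deterministic
rule `(HE4 >= 78 and advanced stage) or (HE4 >= 135 and BMI < 31.5)`
plus 10% label noise.  Its marginals are chosen for *identifiability*,
not realism: the binary stage driver is Bernoulli(0.7) and HE4 uses
log-sigma 0.6, which makes the root cut at 78 population-optimal by a
decisive margin (per-row impurity decrease 0.154 at 78 versus 0.065 at
135).  Under the study emulator's own marginals (15% advanced stage,
log-sigma 0.83) the two clauses carry nearly equal impurity and the
optimal first split genuinely sits at 135 — a recovery test there would
measure distribution geometry rather than implementation correctness.
This analysis is the reason the fixture exists separately from the
study emulator.

## Numerical and design notes

- Split deltas are computed from integer-exact cumulative sums
  (`s - s^2/n` form), so the grower agrees bit-for-bit with a
  brute-force enumeration oracle, ties included.
- The split scan has a numba-compiled kernel with an equivalent pure
  numpy fallback; both implement identical arithmetic and tie rules.
- Conservation laws hold exactly: leaf positives sum to cohort
  positives (integer arithmetic), and root impurity telescopes into
  split decreases plus leaf impurities to 1e-12.
- All randomness flows through numpy `SeedSequence` trees keyed by
  user seeds; every fit, forest, and pipeline run is reproducible
  bit-for-bit, and the run manifest records the seeds and parameters.
- Missing-value routing ties (equal observed counts on both sides) go
  left.
- `cost_complexity_path` collapses all nodes attaining the minimal g
  simultaneously, keeping alphas strictly increasing; a zero-gain first
  collapse replaces the full tree as the alpha-0 representative.
- Scaled problem sizes: the test suite and the acceptance script use
  1000 forest trees (not 10,000) and a 200-tree ensemble (not 1000) on
  the n=293 emulator, and B=20 with 5 evaluation folds for the
  pure-noise optimism demonstration; the demonstrated properties do not
  depend on these sizes.

## Known limitations

- No surrogate splits: a covariate missing at predict time routes by
  the training-majority direction only.
- The selection step's AUC is computed on the full original cohort, so
  `selection_auc` must never be quoted as generalization performance;
  use `nested_cv_auc`.
- The logistic baseline drops incomplete rows (about half the emulated
  cohort at the published missingness rates), so its comparison to the
  tree is on a smaller effective sample; the dropped count is reported.
- The generator's covariates are mutually independent apart from the
  biomarker copula and the planted tree; importance rankings on real
  data with correlated covariates will behave less cleanly.
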