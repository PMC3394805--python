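# Methods

## The problem

Breast-cancer outcome prediction can draw on two views of each tumor: a
gene-expression profile (E) and a set of clinical variables (C — grade, age,
hormone-receptor status, outputs of clinical scoring models, and novel
pathology annotations).  `progfuse` implements a controlled comparison of
strategies for combining the two views in a binary poor/good outcome
classification, together with the evaluation protocol needed to make that
comparison unbiased: double-loop cross-validation, a class-imbalance-robust
error metric, paired significance testing, and survival-based endpoints.

Outcome labels come from survival records dichotomized at a horizon (five
years by default): samples with a distant-metastasis event before the
horizon are *poor*, samples with event-free follow-up reaching the horizon
are *good*, and samples censored before the horizon cannot be assigned and
are excluded.

## Classifiers

Five classifiers of increasing complexity, all using poor as the positive
class and resolving every tie toward poor ("believe the positive"):

* **NMC** — nearest mean with the cosine correlation distance
  d(x, y) = 1 − x·y/(‖x‖‖y‖).  Note a structural property exploited nowhere
  but worth knowing: after per-feature z-scoring on the training samples the
  good centroid is exactly anti-proportional to the poor centroid
  (n_p·c_p + n_g·c_g = 0 per feature), so the cosine NMC reduces to the sign
  of cos(x, c_p) — a linear rule anchored at the prevalence-weighted mean.
* **SBC** — naive Bayes with class-conditional Gaussians for continuous
  features (sd floored at 1e-6) and Laplace-smoothed level frequencies
  (pseudocount 1) for discrete ones.
* **3NN** — three nearest neighbors under cosine distance; each neighbor's
  vote is weighted by the reciprocal of its class prior to counter class
  imbalance.  The exact adjustment mechanism is a documented choice isolated
  in one function.
* **SVM** — soft-margin SVM with the cosine correlation kernel (identical to
  a linear kernel on L2-row-normalized inputs); C = 1, rescaled per class by
  N/(2·N_class).  The dual solver is scikit-learn's libsvm wrapper with a
  precomputed kernel.
* **Tree** — greedy binary CART-style tree minimizing weighted Gini
  impurity, written in-package so that tie-breaking is fully specified
  (smallest impurity, then smallest feature index, then smallest threshold;
  thresholds at midpoints of consecutive distinct values; minimum node size
  2; zero-gain splits allowed so that XOR-type structure is still found).
  Variant **Tree1** optimizes depth in the inner loop on all features;
  variant **Tree2** grows unpruned on the top ≤ 200 ranked features with the
  feature count optimized in the inner loop.

## Integration strategies

* **none** — one classifier per view (none_E, none_C).
* **early** — column-wise concatenation EC before ranking and training.
* **intermediate** — per-view models combined inside the classifier with a
  mixing weight α ∈ [0, 1] (α on the expression view, 1 − α on clinical):
  combined cosine distances for NMC, convex combination of posteriors for
  SBC, of per-pair distances for 3NN, and of kernel matrices for SVM (PSD is
  preserved because both weights are non-negative).
* **late** — per-view classifiers fused at the label level: OR calls poor
  when either view does ("believe the positive"), AND only when both do.
* **HybridTree** — a tree whose nodes are NMCs: HybridTree(C) roots a
  clinical NMC and branches with expression NMCs below, HybridTree(E) the
  converse.  Per-node features are re-ranked on that node's samples (top 100
  on E, top 10 on C, capped at the view width); nodes stop at purity, fewer
  than 10 samples, or the depth cap optimized in the inner loop.

Only the classifier × strategy combinations of the study design are
runnable; requesting e.g. an intermediate Tree raises an error.

### Choosing α

α is scanned over 0, 0.01, …, 1.00 using only the training partition.  By
default the α curve is scored on stratified 10-fold cross-validated
predictions *within* the training partition rather than on resubstitution
error: resubstitution systematically favors the noisier view, because with
centroid- and neighbor-type models each training sample contributes to its
own class model and a pure-noise view therefore earns spurious training
accuracy, dragging α toward 0.5.  Cross-validated scoring removes that bias
(a pure-noise clinical view drives the selected α to ≈ 1) while remaining a
training-data-only procedure; `alpha_evaluation="train"` restores plain
resubstitution scoring.  Exact ties in the α curve are resolved by the
continuous class separation of the combined score, then by the smallest α —
so two identical views still yield α = 0 deterministically.

## The evaluation protocol

**Error metric.**  eFPFN = (FP/(FP+TN) + FN/(FN+TP))/2 =
1 − (sensitivity + specificity)/2.  Unlike the raw error rate it does not
reward calling everything majority-class under imbalance.

**Double-loop cross-validation (DLCV).**  Per repeat, a stratified 5-fold
outer split; per outer fold, the training 4/5 is used to (i) rank features
(pooled-variance t-test for continuous, Pearson chi-squared without
continuity correction for discrete; single ascending-p ordering, ties by
column index), (ii) select the feature count (budget 200 for expression or
mixed views, 54 for clinical-only) or tree depth by a stratified 10-fold
inner learning curve (ties to the smallest value), (iii) select α, and
(iv) refit on the whole training partition.  The held-out fifth contributes
one metric value and one out-of-fold prediction per sample.  Feature
normalization (per-feature mean 0 / sd 1, n−1 estimator, zero-variance
features mapped to zero) is fitted on the training partition inside the loop
by default; a flag restores whole-dataset normalization for replication of
analyses that normalized per dataset up front.

For NMC and SBC the inner learning curve over all feature counts 1..budget
is computed in one pass: cosine distances to prefix centroids and naive-
Bayes log-posteriors both decompose into cumulative sums over the ranked
feature order, so the curve costs the same as a single evaluation.  Other
classifiers are refit per candidate count (configurable stride).

**Pairing.**  Repeat r uses seed base+r for the outer split and
base+10^6+r for inner splits, independent of the experiment arm, so all
arms see identical partitions and one-sided paired t-tests on the
(repeat × fold) metric vectors are exactly paired.  Degenerate cases: all-
zero differences give p = 1; a nonzero constant difference gives 0 or 1 by
sign.

**Pre-validation.**  Each repeat yields one out-of-fold prediction per
sample; the per-sample mean over repeats (good encoded 1, poor 0, means of
at most 0.5 going to poor) gives a near-unbiased consensus label used for
Kaplan-Meier curves (lifelines product-limit estimator), the two-group
log-rank test, and the survival fraction at the horizon.

**ROC.**  For score-producing arms, the ROC sweeps all distinct score
thresholds (tied scores move together) with trapezoidal AUC.  Late fusion
has no single score, so its ROC uses joint operating points: for k = 0..N
both per-view rankings (most to least poor-like, ties broken by sample
index) call exactly k samples poor, the labels are fused, and the N+1
(FPR, TPR) points are sorted lexicographically and de-duplicated before the
trapezoid — the fused curve need not be monotone in raw k order.

## The synthetic cohort generator

The generator produces the data structure the analysis assumes, with ground
truth for parameter recovery.  Defaults describe a 300-sample cohort with
1000 genes and 45 mixed-type clinical variables (10 continuous, 20 ordinal,
13 binary, 2 nominal with 5 and 6 levels, expanding to 54 features), ~30%
poor prevalence, and survival records compatible with the five-year rule
(poor: event time uniform on (0.5, 5); good: censoring-free follow-up
uniform on (5, 12); an independent fraction, 10% by default, converted to
pre-horizon censored records to exercise the exclusion rule — only the
dichotomization and the qualitative KM shape matter, so no hazard model is
claimed).

**Latent structure.**  Two standard-normal factors with correlation
`shared_signal_rho` (0.5): a proliferation-like factor carried by the
informative genes (120 by default, fully loading the factor, plus unit
idiosyncratic noise) and a grade-like factor carried by the informative
clinical variables (8 by default, loading 0.7071 — semi-redundant clinical
scores).  The poor class shifts the informative features by
`effect_expression` / `effect_clinical` standard deviations (0.8).

**Outcome model.**  With `clinical_only_signal` off, a single Bernoulli
label shifts both factors.  With it on, the poor label is the OR of two
independent causes: the dominant proliferation-like cause and a smaller
matrix-formation-like cause (marginal prevalence 0.12) that drives a block
of four redundant pathology variables (group N) and nothing else.  Those
variables are therefore generatively independent of every gene — exactly
the complementarity that late-OR fusion exploits — while both views remain
informative about the outcome.

**Skewed marginals.**  Continuous informative features pass through the
monotone map v ↦ (e^{kv} − 1)/k (k = `feature_skew`), giving
(k = 1.4 by default) the heavy right tails of real expression intensities
and pathology scores (most samples low, a high-risk minority strongly
elevated).  This is
not cosmetic: with symmetric marginals the prevalence-anchored cosine-NMC
boundary sits near the projection median, the classifiers call about half
the cohort poor, and at such false-positive-heavy operating points an OR
fusion cannot improve the balanced error (AND can).  Right-skewed features
push the anchored boundary above the median, the single-view classifiers
become conservative poor-callers (FN-heavy), and "believe the positive"
fusion is the operating regime the comparison is about.  Ordinal and binary
variables are produced by tertile/median thresholding of latent draws and
are unaffected by the monotone map; nominal variables are uninformative
equiprobable levels (informative slots are assigned to continuous, then
ordinal, then binary variables).

**What the generator does not emulate:** probe-level identities and real
marginal distributions, missing data (complete cases only), gene-gene
correlation beyond the single shared factor per view, and any hazard
structure beyond the dichotomization.  Tests passing on these cohorts
demonstrate that the pipeline recovers planted structure under the stated
statistical conditions; they are not evidence about any particular real
cohort.

## Study conditions and problem sizes

Default desk-scale protocol: 10 repeats × 5 outer folds × 10 inner folds on
300-sample cohorts; the full-scale 60 repeats is one config value away and
is used where paired significance across seeds is the endpoint (the synergy
recovery study).  The synergy study runs the none_E / none_C / late_OR
nearest-mean arms over 10 cohort seeds at the complementary-signal
conditions (`clinical_only_signal=True`, rho 0.5, effect 0.8, n 300) and
counts the seeds where late-OR beats both single views (one-sided paired
p < 0.05) and where its predicted-good group is purer than both.

## Numerical choices and degenerate inputs

* Zero-norm vectors: cosine distance 1 to everything; zero-norm kernel rows
  give similarity 0.
* Zero-variance features normalize to zero (sd treated as 1); constant score
  vectors give AUC 0.5 with a warning.
* A t-test with a class of fewer than 2 samples, or a discrete feature with
  one observed level, returns p = 1.
* Feature-count and depth ties go to the smallest candidate; rounding of
  mean selected feature counts is half away from zero.
* Discrete levels unseen in a training class get Laplace mass; levels never
  seen in training at all get a pseudocount-only fallback.
* Mean eFPFN requires both truth classes present; stratified folds guarantee
  this for every inner and outer evaluation.

## Known limitations

* The 3NN prior adjustment and the pre-validation tie threshold are
  documented choices where the underlying design admits several readings;
  both are isolated behind single functions.
* Tree building is quadratic-ish in samples per node and is the slowest
  fit; full-scale tree grids are supported but not fast.
* The synergy-recovery result is a property of the generator's study
  conditions (complementary causes, skewed marginals, FN-heavy operating
  points); under symmetric Gaussian features the same pipeline shows late-
  AND, not late-OR, as the better fusion — a geometry worth knowing when
  porting conclusions to other data.
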