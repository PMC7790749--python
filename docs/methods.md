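# Methods

## Problem setting

The package addresses binary pathogenicity classification of rare missense
variants in a fixed panel of disease genes, in the regime typical of
clinically curated panels: a few hundred labeled variants, a few dozen
functional-annotation features with missing values, and a downstream user
who acts only on high-confidence calls. A classifier here is judged not only
on ranking (ROC/PR curves) but on how many variants it can call at a
clinical confidence level and how accurate those calls are, and — because
gold-standard labels are themselves curated — on label-free cohort evidence:
case–control enrichment and patient outcomes.

## Data model and curation

A dataset is one row per unique variant (`chrom-pos-ref-alt` identity, gene
symbol, optional population MAF, binary label, feature vector under a fixed
`FeatureSchema`). Curation rules:

* **Rarity**: keep MAF strictly below the cutoff (default 0.001 = 0.1%).
  Variants absent from the population reference are kept: a large fraction
  of true disease variants are never observed in reference cohorts, and
  treating absence as "not rare" would discard exactly the most informative
  rows. The filter is idempotent and order-preserving.
* **Labels from assertions**: a variant is `pathogenic` only if all its
  clinical assertions are in {P, LP}, `benign` only if all are in {B, LB};
  any mixture across those classes, or any VUS, excludes the variant.
  This is deliberately conservative — conflicting interpretations are
  evidence of uncertainty, not a voting problem.
* **Splitting**: stratified 2:1 train/holdout split. Per class,
  `ceil(n_class · fraction)` rows go to train (the fractional remainder is
  assigned to train), so each class deviates from the target fraction by
  less than one variant; membership is a pure function of the seed.

The TSV feature table is canonical. A read-only VCF path (biallelic records
only, INFO keys mapped to schema features via YAML) exists for convenience;
it produces an unlabeled dataset unless a label INFO key is mapped.

## Classifier

Discrete AdaBoost over depth-limited CART trees (the trees themselves are
scikit-learn `DecisionTreeClassifier`s; the boosting loop, probability
transform and serialization are this package's own):

1. uniform sample weights `w_i = 1/n`;
2. per round `m`: fit a depth-≤`tree_depth` tree on `(X, y, w)`, compute the
   weighted 0/1 error ε_m, set α_m = ½·ln((1−ε_m)/ε_m), multiply
   misclassified weights by exp(2α_m), renormalize;
3. stop early when ε_m = 0 (the round is kept with α capped at ln(10⁶);
   further reweighting is undefined) or ε_m ≥ ½ (the round is discarded —
   a weak learner at chance means boosting has converged or the data are
   uninformative). If the *first* round is already at chance the discarded
   tree is retained with α = 0 so the model object remains valid; it votes
   with weight zero and the predicted probability degenerates to 0.5, with a
   warning and the stopping reason recorded.

**Probability transform.** Pr is the normalized weighted vote
Σ α_m·1[vote_m = pathogenic] / Σ α_m. This choice (over, say, a logistic
transform of the additive margin) is bounded by construction, monotone under
any single tree's vote flip, exactly reproducible from the serialized model,
and easy to reason about in tests. It is *not* a calibrated posterior: vote
shares concentrate near ½ unless the ensemble is confident, which makes the
three-way clinical calls conservative on weakly separated data. Users who
need calibrated probabilities should apply their own calibration layer on
held-out data.

**Missing features** are imputed with per-feature training medians stored in
the model, so a saved model is self-contained. Features that are entirely
missing in training impute to 0 with a warning.

**Defaults**: `n_rounds = 500`, `tree_depth = 3`, α cap ln(10⁶). These are
conventional boosting settings for tabular data of this width; all are
configurable and recorded in the model metadata.

**Serialization** is versioned JSON: schema, imputation vector, per-round
nested split/leaf nodes with α and ε, and training metadata. Loading
validates the version and shape and reproduces predictions bit-for-bit.

## Model selection

Nested cross-validation with stratified folds (per class, shuffled rows are
dealt round-robin, so per-fold class counts differ by at most one). The
inner loop (default 5-fold) grid-searches each candidate's finite
hyperparameter grid by mean out-of-fold metric; the outer loop (default
10-fold) re-tunes per fold, refits at the chosen point, and scores the held
fold. The winner maximizes the mean outer metric. Outer-fold test rows are
never passed to inner fits (checked by an instrumented-candidate test).

Selection metric default: PR-AUC — with class-imbalanced variant panels the
precision–recall view is the more sensitive summary. Ties everywhere break
to the earlier entry (grid order, registry order): determinism is worth more
than an arbitrary coin flip. A failed fit scores −∞ and is logged, never
fatal. The shipped nine-candidate registry (boosted trees, random forest,
L2 logistic, RBF SVM, kNN, naive Bayes, single tree, gradient boosting,
small MLP) spans the major algorithm families; only the boosted-tree entry's
behaviour is contractually specified.

## Thresholded evaluation

Three-way calls at `ThresholdPair` (defaults 0.9/0.1, boundaries inclusive
toward the confident calls, mirroring ≥90% confidence for likely-pathogenic
/ likely-benign assertions). The metric suite counts TP/FP/TN/FN among
high-confidence calls and indeterminates per class; TPR and TNR use the
*full* class sizes as denominators, so an indeterminate call costs
sensitivity — the design goal of the three-way scheme is to make that cost
visible. Two identities hold on every input and are property-tested:

    overall_accuracy = proportion_high_confidence × accuracy_high_confidence
    proportion_indeterminate = 1 − proportion_high_confidence

Zero-denominator rates are NaN and named in an `undefined` list — never
silently 0, which matters for small subgroups. Percentages are produced only
at the reporting layer (half-up, one decimal).

Curve metrics: ROC-AUC is the Mann–Whitney probability (via scikit-learn,
tested against a brute-force pairwise oracle); PR-AUC uses the
average-precision step form rather than trapezoids, which would be
optimistically biased; Brier is the raw mean squared error of Pr (lower is
better).

Classifier comparison on the same variants: a paired permutation test that
swaps the two classifiers' scores per variant (exhaustive over all 2^n
patterns for n ≤ 12, else Monte Carlo with the add-one correction
(b+1)/(n_perm+1)), and the paired DeLong test via placement values with a
normal reference. The subgroup evaluator (e.g. seen vs. unseen variants)
permutes group assignments, enumerating when the number of arrangements is
≤ 20 000.

Prevalence projection: holdout TPR/FNR/TNR/FPR are projected by Bayes' rule
onto a population with pathogenic fraction π:
PPV = π·TPR/(π·TPR+(1−π)·FPR), NPV = (1−π)·TNR/((1−π)·TNR+π·FNR). The rates
are high-confidence call rates (indeterminates excluded from numerator and
denominator alike), so these are predictive values *of the confident calls*;
under full penetrance they are conservative lower bounds.

## Cohort validation

* **Odds ratios**: carrier-based 2×2 tables per gene and stratum (one
  carrier per gene per cohort). OR = (a·d)/(b·c); any zero cell triggers the
  Haldane–Anscombe +0.5 on all four cells, flagged. CIs are Woolf
  (log-scale ± 1.96·SE). A stratum is compared to the all-rare baseline by a
  z-test on the log-OR difference with the sum of the two Woolf variances —
  an independence approximation that is conservative because the strata
  share the reference cohort, and flagged as such.
* **Survival**: Kaplan–Meier product-limit curves (via lifelines), pairwise
  log-rank tests (1 df), and Cox proportional hazards with group indicator
  covariates. Ties are handled by Breslow's method (statsmodels `PHReg`;
  cross-checked against lifelines on tie-free data, where Breslow and Efron
  coincide). A group with no events yields a monotone partial likelihood;
  such contrasts are returned flagged `converged=False` rather than raising.
* **Landmark risk**: the difference of cumulative incidences 1−S(age) at a
  landmark age (default 60), with a percentile bootstrap CI (default 2000
  resamples) over patients resampled within each group. The CI method is a
  pragmatic choice; Greenwood-based intervals would be a reasonable
  alternative but do not extend as directly to the difference of two curves.

## Synthetic generators

All three generators are pure functions of (spec, seed).

* **Feature tables**: bounded [0, 1] scores are Beta-distributed with
  class means separated by the effect size `d` on the logit scale
  (concentration 10); continuous annotations are unit-variance Gaussians
  with the pathogenic mean shifted by `d`; missingness is uniform at
  `missing_rate`. Defaults are the cardiomyopathy curation conditions:
  356 pathogenic + 302 benign variants, 76 features (half bounded scores),
  16 genes assigned round-robin, 45% of variants MAF-absent, the rest
  log-uniform below the 0.1% cutoff, 5% missing entries, `d = 0.25`. The
  default `d` was chosen so that, with 76 weakly informative features, the
  classes overlap realistically (holdout ROC-AUC in the low 0.9s at the
  default sizes) rather than separating trivially; `d = 0` is an exact null
  and `d = 4` is near-separable.
* **Cohort counts**: control carriers ~ Binomial(n_controls, f); case
  carriers ~ Binomial(n_cases, f′) with f′ chosen so the population odds
  ratio equals the requested one (f′ = OR·odds(f)/(1+OR·odds(f))).
* **Survival cohorts**: exponential event ages with hazard
  `baseline_rate × HR` per group and independent Uniform censoring ages.
  Default groups mirror a registry-scale outcome comparison: 1927
  genotype-negative patients vs. 803 carriers of predicted disease-causing
  variants at HR 1.9, baseline rate 1/80 per year. The recovery and
  type-I-error suites use 2000 patients per group with baseline rate 1/50
  and censoring Uniform(20, 80) years, which censors ≈30% of records.

What the generators deliberately do **not** emulate: inter-feature
correlations and the idiosyncratic score distributions of real annotation
tools, per-gene label imbalance, allele-level (vs. carrier-level) counting,
age-dependent hazards, or competing risks. Passing tests therefore
demonstrate correctness of the algorithms under the stated models, not
clinical validity of any retrained classifier on real cohorts.

## Numerical and reporting choices

* All seeds are integers fed to `numpy.random.default_rng` /
  `SeedSequence`; derived seeds stay below 2³¹. Identical seeds yield
  byte-identical JSON reports (keys sorted, floats via `repr`).
* Permutation p-value comparisons use a 10⁻¹² guard on the ≥ comparison to
  absorb float noise in recomputed metrics.
* Exhaustive-enumeration bounds (2¹² swap patterns, 20 000 group
  arrangements) keep the exact branches well under a second.
* Leaf votes in serialized trees break ties toward the benign class (lower
  class index), matching the underlying CART predictor.
* Degenerate inputs are flagged, not guessed at: single-class metric
  denominators are NaN with names listed; zero-variance DeLong comparisons
  return p = 1 (no difference) or p = 0 with a warning; Cox contrasts
  without events are returned non-converged.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses: 500+500 variants at `d = 4` with a 2:1 split
(nested CV: outer 10-fold, inner 5-fold, boosted trees vs. majority
baseline; final model 100 rounds, depth 3); one cohort of 5000 cases /
5000 controls at true OR 5 and carrier frequency 1%; and one survival cohort
of 2000 + 2000 patients at true HR 1.9 with ≈30% censoring, evaluated at the
age-60 landmark with 500 bootstrap resamples. These sizes make every
quantity stable to a few percent while keeping the full script to about a
minute on one CPU.

## Known limitations

* The vote-share probability is uncalibrated (see above); reported PPV/NPV
  projections inherit whatever miscalibration the thresholded calls have.
* The log-OR difference test ignores the shared-control correlation
  (conservative).
* The nested-CV report refits one model per outer fold per candidate; with
  large grids and slow candidates the cost is outer_k × grid × inner_k fits.
* VCF input is read-only and biallelic-only by design; no annotation
  retrieval or transcript mapping is attempted.
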