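# Methods

`digitalmarker` implements a "digital marker" pipeline for rapid
prediction of chemo-drug sensitivity from transcription levels.  A
digital marker is a short ordered gene list, specific to one cancer
type and one drug, whose joint expression pattern predicts sensitivity
via a K-nearest-neighbors model.  This note documents the statistical
procedures, their assumptions, the tunable parameters, and the design
choices made where the procedure was genuinely open.

## Screening

The screen reduces a whole transcriptome (gene-by-sample TPM) to a
ranked candidate list.  Two paths exist because cell-line cohorts carry
continuous IC50 responses while patient cohorts carry binary
effective/ineffective outcomes.

**Cell-line path.**
1. *Expression filter*: keep genes with mean log10(1+TPM) strictly
   greater than 1 across all samples.  The pseudo-count keeps zero TPM
   finite.
2. *Correlation filter*: keep genes whose Pearson correlation between
   TPM and the Z-scores of log IC50 exceeds 0.25 strictly.  By default
   the absolute value |r| is compared: genes whose high expression
   predicts sensitivity correlate *negatively* with IC50, and both
   directions are informative.  A configuration switch
   (`use_abs_correlation=False`) restores the literal signed rule, and
   `log_correlation=True` correlates log10(1+TPM) instead of raw TPM.
3. *Fisher score*: rank genes by the univariate Fisher
   linear-discriminant magnitude between the extreme IC50 tails:
   samples are ordered by Z (ties broken by sample identifier for
   determinism) and the lowest/highest `max(2, floor(0.15 n))` form the
   two groups; the score is |mean_high − mean_low| /
   sqrt(var_high + var_low) on log10(1+TPM), with unbiased variances.
   The square-root form is used; squaring it is rank-equivalent.  If
   both variances vanish the score is 0 for equal means and +inf
   (ranked first) otherwise.

**Patient path.**  The expression filter uses mean log10(TPM) > 0
(no pseudo-count; a gene with any zero TPM fails), and genes are ranked
by −log10 p of a two-sided Mann–Whitney U test of TPM between the two
outcome groups.  The exact null distribution is used when
min(n1, n2) ≤ 8 and the gene has no tied values; otherwise the normal
approximation with tie correction.  Equal p-values break by descending
absolute difference of group medians, then gene identifier.  The
p-values are used purely as a ranking score; no multiple-testing
correction is applied or needed.

**Paired cohorts.**  Two cell-line datasets profiling the same cancer
type/drug are screened independently and their per-gene scores *added*
over the genes surviving the filters in both datasets; the sum orders
the candidate list (ties break lexicographically by gene identifier).
Raw summation is the default; because Fisher scores are not strictly
scale-commensurable across cohorts, a `rank_percentile_sum` mode maps
each dataset's scores to percentile ranks in (0, 1] before adding.

**Stable genes.**  For wet-lab panel design, screened per-drug lists
can be pooled: a gene qualifies as stable when it occurs in strictly
more than 20 drug lists in *each* of the two datasets; genes screened
in only one dataset are excluded.

All log transforms are base 10.  All filter inequalities are strict; a
gene sitting exactly on a threshold is rejected.

## Marker selection

Given the ranked list, the marker is finalized by enumerating its size
m = 1..30 (prefixes of the ranking, in order) jointly with the KNN
neighbor count k = 1..30 under stratified 5-fold cross-validation.
Features are log10(1+TPM), standardized per gene with
training-fold statistics; distances are Euclidean; distance ties break
by training-sample index order, and classification vote ties at
p = 0.5 resolve to "ineffective" (conservative toward a non-treatment
signal).  The fold score is the test-fold AUC with ranking score
−predicted Z (regression; true label = Z ≤ z_threshold, strict ≤, with
−1.0 as the default threshold and −0.6 as a common alternative) or the
ineffectiveness-probability complement (classification).  The (m, k)
pair with the highest mean AUC wins; ties prefer smaller m, then
smaller k (parsimony).  The returned marker refits its standardization
and training reference data on the full cohort.

**Leakage and the nested estimator.**  Enumerating on a ranking
computed from the full dataset lets the screen see the evaluation
folds, and maximizing over a ~900-cell (m, k) grid adds a winner's
curse: at n = 60 the maximum of that many noisy fold-mean AUCs sits
well above 0.5 even with no signal.  The default mode is therefore an
*optimistic* model-selection score, reported as `cv_auc`.  For an
honest generalization estimate the package provides `nested_cv_auc`:
outer stratified folds are held out for evaluation only, and inside
each outer training set the screen is re-run and (m, k) selected by
inner CV.  Its pooled outer AUC concentrates near 0.5 under a null
cohort — the property the test suite verifies — and is the right
quantity to quote for expected performance on new samples.

**Cross-prediction regimes.**  For paired cohorts three regimes are
implemented: (1) combined-ranking selection evaluated within each
dataset; (2) ranking, selection and evaluation within the same
dataset; (3) cross-prediction, where the gene ranking *and* the
selected (m0, k0) come from the other dataset and the evaluation
dataset only runs fixed-hyperparameter 5-fold CV.  In regime 3 the
evaluation data informs no model decision, so its AUC is honest: near
0.5 when the two datasets share no true signal genes, high when they
do.

## Evaluation metrics

Reports carry accuracy, precision, recall, specificity,
support-weighted F1, AUC and the confusion counts, with the
sensitive/effective class as positive.  AUC is computed by the exact
rank-sum identity (equal to concordant + 0.5·tied pairs over
n_pos·n_neg), so monotone rescaling of scores cannot change it.
Zero-denominator metrics (e.g. precision with no positive calls)
report 0.

## qPCR conversion and recommendation

qRT-PCR quantification cycles are linear in log abundance:
with dCq = Cq(target) − Cq(reference gene, GAPDH by default),

    log10(TPM + 1) = slope · dCq + intercept,

defaulting to slope −0.3995 and intercept 5.6974 (an SW620
calibration).  `fit_conversion` refits both coefficients by ordinary
least squares from paired (dCq, TPM) measurements; the sign convention
makes the slope negative (more cycles = rarer transcript).  The
inverse conversion floors TPM at 0, since values below the line's root
(dCq = intercept/−slope ≈ 14.26 cycles) would otherwise be negative.
When Cq values are generated noiselessly from TPM the qPCR prediction
path selects bit-identical neighbors to the TPM path.

Predicted log IC50 values are turned into per-drug calls by
standardizing against the cancer-type cohort ("relative Z", population
SD, log scale): strictly below −1 is "sensitive" (green), strictly
above +1 "non-sensitive" (red), otherwise "neutral" (black); exact ±1
stays neutral.  On the classification path the ineffectiveness
probability maps onto effective / intermediate / ineffective zones;
the zone cuts default to equal thirds (1/3, 2/3) and are
configuration-exposed, since the decision bands are otherwise
unquantified.

## Synthetic data

The generators exist so every stage is testable without cohort
downloads.  Per-sample latent sensitivity z ~ N(0,1); each of the
(default 10) signal genes moves its log10(1+TPM) by `effect_size` per
unit z, with directions alternating ±1 so both orientations of the
correlation-filter policy are exercised; decoy genes are noise around
a log-normal background.  ln IC50 = 1.0·z + 2.0 (μM), so standardized
log IC50 recovers z exactly.  Defaults: 2000 genes, 60+60 samples,
noise SD 0.4 on the log scale and effect size 0.6 (= 1.5× noise SD);
background baselines N(0.7, 0.7) so roughly a third of decoys clear
the cell-line expression filter; signal-gene baselines N(1.8, 0.3),
since a usable marker must be robustly expressed; dataset B adds a
+0.3 log10 batch shift, additive only, which preserves cross-dataset
rank structure and makes cross-prediction a meaningful test.  Patient
cohorts assign balanced binary outcomes first and shift signal genes
by `effect_size` between classes; their TPM is strictly positive
(10^logv), so the strict patient expression filter reduces to mean
logv > 0, whereas cell-line TPM is 10^logv − 1 floored at 0 and does
contain zeros.  qPCR readouts invert the conversion model per gene and
add Gaussian cycle noise around a constant reference Cq (20 cycles).

What the generator does *not* emulate: GDSC/CCLE marginal
distributions, gene–gene correlation structure, dropout patterns, or
library-size artifacts.  Passing tests therefore demonstrate that the
algorithms are implemented correctly and behave honestly under known
signal and known null — not that markers screened from real cohorts
will attain comparable accuracy.

## Numerical choices and degenerate inputs

* Z-scores of IC50 standardize the natural-log IC50 with population SD
  (GDSC convention); log10 and raw scales are available by
  configuration.
* Duplicate gene rows collapse by mean with a logged warning; genes
  with missing values are dropped (no imputation), consistent with the
  filter-then-score flow which assumes complete vectors.
* Zero-variance genes are excluded from correlation; constant
  standardization SDs fall back to 1 inside CV folds (the centered
  feature is then identically 0).
* A CV fold whose test part contains one class contributes no AUC; the
  mean is over defined folds.
* Replicate qPCR columns (`<gene>_<n>` suffix) collapse by mean before
  dCq.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
generator's default conditions over 20 seeds per property, with 1000
random instances per oracle-equivalence check; these sizes give stable
medians while keeping a full run in the low minutes on one CPU.

## Known limitations

* The default `cv_auc` is a model-selection score, not a
  generalization estimate; use `nested_cv_auc` for the latter.
* The Mann–Whitney asymptotic branch applies a continuity correction;
  at moderate n its p-values differ slightly from the exact ones, which
  only matters for ranking when p-values tie.
* The conversion model is a single global line; per-gene amplification
  efficiencies are not modeled.
* No alternative learners (elastic net, neural networks) are provided;
  the KNN model is the point of the exercise.
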