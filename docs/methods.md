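# Methods

## The problem

Wrapper feature selection for small-n binary classification of omics tables:
a few hundred samples, up to a few hundred numeric features (gene-expression
profiles, peptide descriptors), of which only a small subset carries class
signal. Recursive feature elimination (RFE) with a random forest produces a
*trace* of nested candidate subsets with an accuracy for each; the open
question this package addresses is the **decision variant** — the rule that
turns that trace into one final subset — and how to make that decision
robustly inside cross-validation.

## The procedure

**Normalization.** Each feature is rescaled to [−1, 1] by the affine map
f′ = 2·(f − f_min)/(f_max − f_min) − 1, with f_min/f_max the column extremes
of the *training* portion only. Held-out values are transformed with the
training parameters and may leave [−1, 1]; they are not clipped. Constant
training columns map to 0 (the feature carries no information, and the
alternative is a division by zero). Missing values are a load-time error,
never imputed: the intended inputs are preprocessed complete matrices.

**Random forest and importance.** Forests use scikit-learn's
`RandomForestClassifier` with the R `randomForest` classification defaults:
500 trees, √p candidate features per split, unlimited depth. Importance is
**out-of-bag permutation importance** (mean decrease in accuracy): for each
tree, the samples absent from its bootstrap draw are scored as-is and again
with one feature's values permuted among them; the drop in accuracy,
averaged over trees, is the feature's score. The score is used unscaled —
only the ranking matters. scikit-learn does not expose OOB permutation
importance, so the bookkeeping is done here: each tree's bootstrap draw is
regenerated from its stored seed (the same uniform-with-replacement draw the
library makes, pinned by a unit test against the library's own generator),
and all permuted copies for a tree are scored in one stacked predict call,
which keeps the loop fast at small n. Importance ties break lexicographically
by feature name so rankings are deterministic.

**Elimination trace.** With step size 1 (the default), each iteration fits
one forest on the training split restricted to the surviving subset; that
forest yields both the importance ranking and the predictions on the
evaluation split recorded as the subset's balanced accuracy. The least
important feature is dropped and the loop repeats down to one feature, so p
features give exactly p recorded subsets. An empty subset has no classifier,
so the trace stops at size 1. For step > 1 the last drop removes fewer
features rather than overshooting. Plain accuracy can be recorded instead of
balanced via `ClassifierConfig(metric="plain")`.

**Decision variants.**

- **HA**: the step with the highest recorded accuracy. Ties go to the
  smaller subset — compactness is the point of selection.
- **pct-HA** (default 90%): the *smallest* subset whose accuracy is ≥
  pct × (highest accuracy). The comparison uses ≥ at full float precision;
  the threshold is only rounded (half-up, two decimals) for reporting. The
  "smallest qualifying subset" reading is the one consistent with the
  variant's purpose; a literal argmax at the reduced threshold would be the
  same step as HA.
- **PreNum**: the step whose subset has exactly the preset size —
  equivalently the top-PreNum features of the ranking the drop order induces.
  If no step has that size (possible when step > 1) the error names the
  available sizes.

**Cross-validated voting.** The data is split into stratified tenths; each
fold holds out one tenth (X4) and deals the rest into three stratified parts
(X1, X2, X3; equal thirds by default). RFE trains on X1∪X2 and scores every
subset on X3; the decision variant picks that fold's subset from the trace.
A feature's vote v_f is the number of folds that selected it. For each
threshold υ₀ in 0 … n_folds−1 the candidate final subset is the features
with v_f **strictly greater than** υ₀ — candidate sets are nested and shrink
as υ₀ grows, and adjacent thresholds with identical candidates are evaluated
once. Each non-empty candidate set is scored by retraining per fold on
X1∪X2∪X3 (restricted to the set) and predicting that fold's X4; the mean
balanced accuracy across folds decides, with accuracy ties going to the
larger υ₀ (the more compact set). This chooses υ₀ automatically. Normalization
is refitted per fold on X1∪X2∪X3, so X4 never influences scaling.

**Reporting.** Final metrics pool the X4 confusion counts across the ten
folds (TP+FN = all positives, TN+FP = all negatives) and derive
sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP), balanced
accuracy = their mean. Percentages are held unrounded internally and
reported half-up to two decimals. A no-selection baseline (same folds, all
features) is always computed alongside. Pooling is used rather than
averaging per-fold percentages because it remains well defined when a fold's
X4 is small; per-fold averaging is what the threshold sweep itself uses,
since the sweep compares sets, not samples.

## Randomness and determinism

One master seed drives everything: fold assignment, each fold's per-iteration
forest seeds, and the sweep's scoring forests each receive seeds derived via
`numpy` `SeedSequence` spawning from (master seed, component key). Two runs
with the same arguments produce bit-identical reports; the report echoes the
full configuration needed to replay it.

## The synthetic generator

`simulate.generate` emulates the target data shape: n samples with an exact
round(class_balance·n) positive count (default 45/111, the imbalance of a
111-drug toxicogenomics screen), p features of which `n_informative` are
drawn from class-conditional Gaussians with means ±effect_size/2 and unit
noise, the rest standard Gaussian independent of the label. Optional blocks
of informative features share a latent factor (pairwise correlation 0.7) to
mimic co-expressed genes — the regime where redundant features split votes.
Feature positions are shuffled and names are uninformative; ground truth is
returned out of band. The generator does *not* simulate microarray technical
artifacts, batch effects, heavy-tailed expression noise, or sequence-derived
feature structure, so passing recovery tests demonstrate the machinery works
under the stated model, not performance on any real assay.

## Problem sizes used in the test suite and acceptance script

Test runs use deliberately small problem sizes so the whole suite finishes in minutes on one core. The recovery study uses n = 200, p = 100,
5 informative features at effect size 1.5, 10 folds, 10 seeds; the null
calibration uses effect size 0 at n = 100, p = 15, 20 seeds; trace-contract
checks use p = 50. These pipeline-scale runs use 15–20 trees per forest:
at n ≈ 130 training samples per fit, rankings from 20 trees are noisy per
step but the procedure aggregates over ~100 elimination steps and 10 folds,
which the recovery results bear out. Library-default forests (500 trees) are
recommended for real analyses. The acceptance script runs the same study
condition once per decision variant (PreNum preset to 12).

## Known limitations

- The υ₀ sweep and the final report both use the X4 parts; the chosen
  threshold's reported accuracy is therefore optimistically biased — it is a
  max over up to n_folds correlated candidates, each measured with sampling
  noise that scales as 1/√n. The null-calibration test measures this
  directly: on pure-noise data at n = 100 the reported balanced accuracy
  averages ≈ 61% rather than 50%, i.e. roughly a +1.5-sd inflation, and the
  test flags it. A fully unbiased report would need an outer held-out layer
  the procedure does not define; with no such layer, reported accuracies on
  small samples should be read net of this bias.
- Importance recomputation happens on X1∪X2 at every elimination step;
  with very small folds the OOB sets get thin and rankings degrade before
  accuracy does.
- Binary classification only; one label column; no weighting, no missing
  data, no multi-class or regression mode.
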