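# Methods

`sigpanel` implements a discovery pipeline for multiplexed antibody-microarray
serum profiling: spot-level preprocessing, two-step normalization,
differential expression, and a supervised signature search built on linear
support vector machines with backward feature elimination scored by a
Kullback-Leibler (K-L) classification error. This note records the model,
its assumptions, the tunable parameters, the synthetic data the pipeline is
validated on, and the numerical choices made where the procedure left room.

## The measurement model

Each serum sample is incubated on one subarray of a printed slide; each of
the `n_antibodies` capture antibodies is printed in 3 replicate spots.
A scanner reports a foreground `intensity` and a local `background` per
spot. All modeling after background subtraction happens in log10 intensity
units, where technical effects (day-to-day printing drift, array-to-array
scale) are well approximated as additive offsets and multiplicative
replicate noise becomes homoscedastic.

## Preprocessing

1. **Background subtraction.** `intensity − background` per spot, floored
   at 1.0 linear unit so the subsequent log10 stays defined. The floor is
   a design choice: near- or sub-background spots carry no usable signal
   and are mapped to log10 = 0 rather than propagated as negative values.
2. **Replicate aggregation (15% CV rule).** The value for a
   (sample, antibody) is the mean of its 3 background-subtracted
   replicates, unless their coefficient of variation (100·sd/mean, sample
   sd, linear scale) exceeds `cv_cutoff` (default 15%). In that case the
   replicate farthest from the 3-replicate mean is dismissed and the
   remaining 2 averaged — dropping the farthest is the dismissal that
   maximally reduces the CV. With only 2 replicates present no dismissal
   is attempted (there is no principled way to pick one); with fewer than
   2 the value is flagged and floored. 
3. **Failed-sample exclusion.** A sample whose median log10 intensity has
   a robust z-score (vs. the cohort median, scaled by 1.4826·MAD) below
   `z_cutoff = −4` is excluded as near-signal-free. When the cohort MAD is
   0 the rule degrades to an absolute floor (median log10 < 1). The
   robust-z formulation is this package's own rule for an exclusion the
   assay protocol performs by inspection.
4. **Round normalization (subtract group mean).** For antibody *j* and
   sample *i* run in round (analysis day) *r*:
   `x'_ij = x_ij − mean_{i'∈r}(x_j) + mean_all(x_j)`.
   After the step, every (antibody, round) mean equals the global antibody
   mean exactly (checked to 1e-9); day-to-day drift is removed without
   changing the overall intensity scale.
5. **Array scaling.** Arrays differ in overall brightness (e.g. sample
   autofluorescence). A reference set — the `lowcv_fraction` (default 20%)
   of antibodies with the lowest cross-sample CV, computed on the linear
   scale, ties broken by antibody id — defines a per-sample offset: the
   sample's mean log10 level over the reference set minus the grand mean
   of that quantity. Subtracting the offset in log space is exactly a
   per-array multiplicative scaling factor on the linear scale; keeping
   both normalization steps in log space keeps them composable and
   order-stable. Computing the reference CV after round normalization is a
   choice; a config switch is not offered because the effect is second
   order once rounds are centered.
6. **Preanalytical screening.** Per factor (clinical center, gender, age
   quartile, subarray position, round), a one-way ANOVA per antibody; the
   report lists the fraction of antibodies with p < 0.01. No multiplicity
   correction is applied — this is a screen whose expected null fraction
   (≈1%) is itself the reference point.

## Differential expression

Per antibody, a two-sided pooled-variance Student's t-test between the two
contrast groups (Welch available via `equal_var=False`); fold changes are
reported as log10 differences and as linearized `10^Δ`. Benjamini-Hochberg
step-up q-values control FDR (delegated to `statsmodels`; an independent
brute-force step-up oracle guards it in the tests). Multi-group comparisons
use one-way fixed-effects ANOVA, vectorized across antibodies. Degenerate
zero-variance antibodies get p = 1 when group means agree (no evidence) and
the smallest representable p when they differ (the limit of the statistic).
For visualization, antibodies passing `p < 1e-10` are z-scored per antibody
(variance normalization, the convention of array-PCA tools) and projected
onto 3 principal components; the sign of each component is fixed by making
its largest-magnitude loading positive so coordinates are reproducible.

## Signature discovery

The engine addresses a fact t-tests ignore: immunoregulatory serum proteins
are correlated, so individually significant markers carry overlapping
information. Backward elimination removes, at each round, the antibody
whose *removal* least harms classification, which prunes redundant markers
first and leaves a panel of complementary ones.

- **Splitting.** Per repeat (default 10), a stratified split assigns
  `floor(2n/3)` of each group to training, the rest to test. Repeats use
  independent seed-derived streams.
- **Classifier.** Linear-kernel C-SVC with cost 1 (libsvm). Features are
  standardized with training-set statistics only; the standardization is
  part of the frozen model. The first-listed contrast group (the disease
  group) is the positive class: decision values > 0 predict it.
- **K-L error.** Decision values are mapped through the logistic link,
  `p_i = 1/(1+exp(−d_i))`, clipped to `[1e-6, 1−1e-6]`, and the error is
  the summed K-L divergence from the point-mass truth to the predicted
  probability — the cross-entropy `Σ −log p_i` (truth positive) /
  `−log(1−p_i)` (truth negative), in nats. A panel of *n* maximally
  uncertain predictions scores `n·ln 2`; a clipped-perfect one ≈ `n·1e-6`.
- **Cross-validated decisions.** During elimination, decision values come
  from internal stratified 5-fold CV on the training set (each sample
  scored by the fold model that did not see it). Resubstitution values
  would drive the K-L error toward zero for any sufficiently large panel
  and destroy the selection signal. Fold assignment is drawn once per
  elimination round and shared by all candidates in the round, so
  candidates are compared on identical folds; `k` is reduced when it
  exceeds the minority-class count.
- **Elimination.** From the full panel down to one antibody: every
  remaining antibody is tentatively removed, the reduced panel's K-L error
  computed, and the argmin removed (ties broken lexicographically by
  antibody id). The exhaustive O(N²) candidate sweep is the faithful
  procedure and the default. Per fold and round, the current panel is
  standardized once; dropping a candidate column afterwards is identical
  to standardizing the reduced panel, which keeps the sweep affordable.
  The hot loop calls libsvm through a thin internal wrapper whose
  decision values are asserted (in tests) to match the public
  `SVC(kernel="linear")` exactly.
- **Endurance scores and consensus.** An antibody removed at round *k* has
  endurance *k* (first out = 1, last survivor = N). The mean endurance
  over repeats ranks antibodies; the top 25 form the consensus panel, and
  the number of distinct target antigens among them is reported separately
  (several clones may target one antigen). Score sums are conserved at
  N(N+1)/2, which the tests assert.
- **Panel sizing.** Per trace, the K-L curve (error vs. panel size) is
  minimized; ties go to the smaller panel (parsimony).
- **Frozen evaluation.** Per repeat, a model on the 25 longest-surviving
  antibodies is trained on the training set, frozen, and applied to the
  held-out test set: AUC as the Mann-Whitney rank statistic (ties ½), and
  sensitivity/specificity/PPV/NPV from the confusion matrix at decision
  threshold 0.

An open question in the procedure is whether the K-L error should instead
be a divergence between class-conditional decision-value densities. The
cross-entropy formulation was chosen because its magnitudes behave
correctly at both extremes (chance ⇒ `n·ln 2`, separation ⇒ ~0) and it
needs no density estimate on ~50-sample folds; `kl_error` is a free
function so alternative formulations can be swapped in.

## Synthetic cohort generator

No public deposition exists for the serum cohort this pipeline targets, so
validation runs on synthetic data reproducing the study design's structure:
338 samples (156 cancer / 152 other pancreatic disease / 30 nonpancreatic
controls; head 97, body 16, tail 10, other 16, unspecified 17 tumor
subsites), 5 hospitals, 5 analysis rounds × 8 slides × 13 subarrays,
293 antibodies × 3 replicate spots.

The generative model per (sample, antibody):

```
level  = baseline_j + group/subsite effect + N(0, σ_bio)
         + round_offset(r) + array_offset(a)        [log10 units]
spot   = 10^level · (1 + ε) + background,  ε ~ N(0, σ_rep)
```

Defaults: antibody baselines `N(3.0, 0.5)` log10; biological spread
σ_bio = 0.15; replicate noise σ_rep = 0.08 with 2% outlier spots ×1.4
(together calibrated so the mean replicate CV lands near the platform's
observed ~8.3%); round offsets `N(0, 0.05)` with the first round inflated
×3 (the worst printing day); per-array offsets `N(0, 0.1)`; background
`N(100, 10)` linear units; two benign-disease samples attenuated ×0.01 to
emulate near-signal-free failures. Planted group effects are additive in
log10; the default planted effect size of 0.5 log10 (0.8 in the recovery
experiment) keeps markers recoverable but not trivially separable at small
group sizes. Ages follow the per-group means/sds of the study population;
gender and age carry no expression effect by default, so the preanalytical
screen has a true null to calibrate against.

What the generator does **not** emulate: antibody cross-reactivity,
spot-morphology artifacts, scanner saturation, spatial gradients within a
slide, and correlated marker blocks beyond the planted effects. Passing
the recovery experiments therefore demonstrates that the *procedure* is
correct and well calibrated, not that any particular serum signature is
reproducible — the published cohort itself is not available to rerun.

## Problem sizes

The canned validation experiments use scaled problem sizes chosen to make
repeated end-to-end runs routine on a single core: recovery and null
experiments use 60 cases / 20 controls over 100 antibodies (10 planted at
0.8 log10 for recovery), 10 split repeats; the batch and failed-sample
checks use 100 and 75 samples over 60 antibodies; the CLI demo
(`sigpanel simulate+run`) uses 3×24 samples over 40 antibodies with 3
repeats. The generator scales to the full 338×293 design
(`sigpanel simulate` writes it by default); elimination cost grows as
O(N²) SVM fits per repeat, so full-size discovery is an overnight-scale
computation by design.

## Numerical choices and degeneracies

- Ties are broken lexicographically by antibody id everywhere a ranking is
  cut (elimination argmin, top-k tables, consensus panels, reference-set
  selection), making all outputs order-independent and reproducible.
- All randomness flows through named streams derived from one seed via
  `numpy.random.SeedSequence.spawn`, so components (design, noise, splits,
  folds) are independently reproducible.
- The frozen `PanelSVC` uses a tightened libsvm tolerance (1e-6) since its
  coefficients are reported; the elimination loop keeps libsvm's default
  1e-3, where only the K-L ranking of candidates matters.
- Zero-variance features standardize with sd = 1 (they contribute nothing
  to the SVM); a test set missing one class yields NaN AUC with point
  metrics still reported; an ANOVA factor with fewer than two levels is
  skipped with a note.

## Known limitations

- The elimination oracle equivalence is only tractable at small N; at full
  scale correctness rests on the shared code path plus the per-round
  invariants.
- The replicate-dismissal rule assumes at most one aberrant replicate per
  triplet, which matches the CV-cutoff formulation but cannot repair two
  bad spots.
- The K-L formulation is one defensible reading of an under-specified
  procedure (see above); elimination orders under other formulations may
  differ even when final panel quality does not.
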