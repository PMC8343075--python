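# Methods

`tractsvm` implements an along-tract ("tractometry") classification
procedure for two-group diffusion MRI studies, in the style used to ask
which white-matter tracts, diffusion properties and tract regions
discriminate MCI patients who later convert to Alzheimer's disease (C) from
those who remain stable (NC). This note documents the models, the
procedure, the parameters that matter, and the choices made where the
design was genuinely open.

## Tract profiles

The unit of data is the *tract profile*: one diffusion property (FA, MD,
RD or AxD; FA dimensionless, diffusivities in 10⁻³ mm²/s) sampled at 100
equidistant nodes along a tract's core trajectory, for each of 20 canonical
tracts. Node indices are 1-based (1..100) everywhere, including reports.

### Profiling from streamline bundles (`tractsvm.profiling`)

Given a bundle of fibers (3-D polylines with per-point scalars):

1. **Orientation**: fibers are flipped to match the first fiber's
   orientation (endpoint distances, ties keep the original direction).
2. **Resampling**: each fiber is resampled to *n* points equidistant in arc
   length; geometry linearly along the polyline, scalars with a cubic
   spline in arc length (linear below 4 distinct points, where a cubic is
   underdetermined).
3. **Core trajectory**: pointwise mean of the resampled fibers, with a
   per-node 3×3 positional covariance (ddof = 1; a tiny ridge keeps
   degenerate nodes well-posed).
4. **Cleaning**: iteratively (max 5 passes) remove fibers with arc length
   above mean + 4 SD of bundle lengths, then fibers whose *core-deviation
   score* — the mean over nodes of the Mahalanobis distance to the core —
   exceeds 5. Mahalanobis distance is already expressed in SD units of the
   bundle's positional spread, so "more than five standard deviations from
   the core" is the direct threshold score > 5; no second-order statistics
   of the scores are involved. Statistics are recomputed after each pass
   until no fiber is removed.
5. **Profile**: at each node, the profile value is the weighted mean of
   fiber values with Gaussian weights w = exp(−d²/2) of the Mahalanobis
   distance d to the core, normalized per node. Profiles are therefore
   convex combinations of fiber values; an unnormalized weighted sum would
   scale with fiber count and is not used.

The per-fiber aggregation of node distances into one deviation score (mean
over nodes) and the exact weight kernel are open choices in the source
procedure; both follow the automated-fiber-quantification lineage.

## Classification engine (`tractsvm.classify`)

For one tract/property, the feature matrix is subjects × 100 nodes
(subjects × 400 for the concatenated "ALL" feature set). Classification is
nested leave-one-out cross-validation; within each fold, with the held-out
subject excluded from *every* fitted quantity:

1. **Normalization**: per-feature z-scoring with training mean and sample
   SD (n−1 denominator); the held-out row is transformed with the training
   statistics. A constant training feature is an error.
2. **RFE with correlation-bias reduction** on the normalized training data,
   eliminating one feature per iteration (finest granularity) until 10
   remain. Ranking criterion for the nonlinear SVM:
   ΔJ(i) = ½ aᵀK a − ½ aᵀK⁽⁻ⁱ⁾a, with a the dual coefficients (labels
   folded in) held fixed and K⁽⁻ⁱ⁾ the kernel recomputed without feature i.
   For the RBF kernel K⁽⁻ⁱ⁾ = K ∘ exp(γ D_i) elementwise (D_i the squared
   difference matrix of feature i), so one precomputed per-feature factor
   serves both the ranking of every candidate and the kernel update after
   elimination; kernels are held in packed upper-triangle form. A
   brute-force oracle that retrains nothing and recomputes each reduced
   kernel from scratch is kept in the code base (`rfe_delta_j_oracle`) and
   pinned against the fast path in the tests.
   **CBR**: features forming a correlated group — pairwise |r| ≥ 0.9 on the
   training data, closed transitively — are scored by removing the whole
   group, and the group score is assigned to each member. This prevents
   correlated features from masking each other (removing one member alone
   barely changes the kernel, underestimating all of them). The
   lowest-scored feature is then eliminated; exact ties (group members
   share one score) eliminate the higher node index so the lower-indexed
   node is kept, making reruns deterministic. The published description of
   the CBR step is one clause; this group-removal scoring is a faithful
   reconstruction, and `use_cbr=False` gives plain SVM-RFE for comparison.
3. **SVM**: RBF kernel, C = 1, trained on the 10 selected nodes; the
   held-out subject is classified by the sign of the decision score
   (positive ⇒ converter).

**Hyperparameters.** No inner tuning loop is used — an 87-subject LOOCV
cannot support nested tuning without changing the procedure. γ is set to
1/(d₀ · pooled feature variance) of the full normalized training matrix of
the fold (pooled variance is 1 by construction, so γ = 1/d₀ with d₀ the
initial feature count) and held fixed through RFE and the fold's final
model; fixing γ within the fold is also what makes the ΔJ criterion
well-defined. The SVM solver is deterministic, so identical cohorts give
identical results with no seed.

The hot loop trains thousands of small SVMs; it calls scikit-learn's
low-level libsvm binding directly (estimator validation dominates the cost
otherwise) with a test pinning its dual solution to `sklearn.svm.SVC` and a
fallback to the standard estimator.

## Evaluation (`tractsvm.evaluate`)

* **Accuracy** = (TP + TN)/N over the pooled folds, converters positive.
* **AUC**: rank-based area from the pooled LOOCV decision scores, ties ½.
  Pooled-score ROC is used because per-fold ROC is undefined for single
  held-out subjects; it makes AUC genuinely independent of the accuracy
  (a pair can be accurate but badly ranked, or vice versa).
* **Chance threshold**: the smallest two-decimal accuracy t such that a
  Binomial(N, ½) classifier exceeds t with probability ≤ α; for N = 87,
  α = 0.05 this is 0.59, computed exactly. The coin-flip null deliberately
  ignores the 53/34 class imbalance (a constant majority-class guesser
  scores 0.609); this is a property of the screening convention and is
  documented rather than corrected. Empirically, on label-independent
  cohorts this pipeline's LOOCV collapses to the majority class, landing at
  0.609 — exactly the upper edge of the exact central 95 % binomial band.
* **Predictive screen**: accuracy strictly above the chance threshold AND
  AUC strictly above 0.6 ("greater than" is strict on both).
* **Permutation test**: labels are permuted preserving the class counts,
  and the *entire* pipeline (normalization, RFE, SVM) is re-run per
  permutation; default 1,000 permutations, one RNG seed for all shuffles.
  Two p-values are reported: the one-sample t-test of the observed accuracy
  against the null accuracies (two-sided; the direction and degrees of
  freedom of the published test are unstated), and the empirical
  p = (1 + #{null ≥ observed})/(n_perm + 1). The empirical p is preferred:
  the t-test treats the null draws as a sample and is anti-conservative.
  Because LOOCV accuracy is discrete and ties count in the null's favour,
  the null distribution of the empirical p is stochastically *larger* than
  uniform (valid but conservative); the calibration tests assert exactly
  this dominance rather than literal uniformity.

## Regions (`tractsvm.regions`)

For each surviving tract/property: the per-node RFE selection frequency
across folds (10 selections per fold) gives a histogram; nodes selected in
≥ 50 % of folds are candidates (threshold configurable — the source
procedure never quantifies "most selected"); candidates are tested with
pointwise pooled-variance t-tests (df = N − 2) under Benjamini–Hochberg FDR
at q = 0.05 (family = the candidate nodes by default; a switch tests all
100); candidate ∩ significant nodes, grouped into maximal consecutive runs,
are the reported regions. The final classifier pools the region nodes
across tracts/properties into one feature matrix and runs the identical
LOOCV pipeline (RFE to min(10, n_features)); reported "final selected
nodes" are the union over folds, which can exceed 10 when folds disagree.

## Cohort statistics (`tractsvm.stats`)

Pooled-variance two-sample t from (n, mean, SD) summaries (df = n₁+n₂−2;
Welch optional) and the Pearson chi-square on 2×2 tables, uncorrected by
default (the Yates correction is a flag). On the reference cohort table the
age comparison gives t(85) = 1.146 and the cardiovascular-history table
X²(1) = 0.36 from the printed summaries.

## Synthetic cohorts (`tractsvm.synthetic`)

The generator emulates the study conditions: 34 C / 53 NC subjects by
default; 100-node profiles per (tract, property); baselines FA 0.45 (SD
0.06), MD 0.80 (0.06), RD 0.60 (0.06), AxD 1.20 (0.08), diffusivities in
10⁻³ mm²/s — typical white-matter values, and only the relative structure
matters to the pipeline. Along-tract noise is a stationary Gaussian process
with squared-exponential correlation, correlation length 5 nodes: real
tract profiles vary smoothly at about this scale; the covariance is a
stated default, not fit to data (no public distributional description of
real node profiles exists to fit against). Group effects are additive mean
shifts of d × baseline SD on converter rows over a node interval of one
tract/property; positive d raises converter values (e.g. elevated
diffusivity). FA is clipped to (0, 1) and diffusivities to > 0; with the
default baselines the clip is essentially never active. Demographics (age,
sex, MMSE) are optional and independent of the profiles.

The canonical benchmark (`benchmark_config`) implants d = 1.5 effects on
axial diffusivity in three tracts — right cingulum-hippocampus nodes
90–100, right IFOF 37–45, left ILF 1–10 and 80–90 — and contains exactly
those three tract/property pairs.

What the generator does *not* emulate: raw DWI, tensor fitting, scanners,
multi-site batch effects, realistic cross-property correlations, or
non-Gaussian tails. Passing tests therefore demonstrate that the pipeline
recovers known structure under idealized smooth-Gaussian profiles, not that
it reproduces any particular clinical result.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks are sized for a desk-scale run, as the package's own
benchmark definitions:

* RFE/oracle agreement: 100 random 6-feature instances.
* Null calibration: 20 cohorts at full size (87 subjects × 100 nodes).
* Permutation calibration: 20 balanced 16-subject, 20-node cohorts at
  n_perm = 99 (the uniform-validity property of a permutation p is
  scale-free; balanced classes keep the null accuracy non-degenerate).
* Region recovery: 25 replicate benchmark cohorts; screens and region
  analysis per replicate, permutation stage omitted there (its behaviour is
  established separately).
* Default `n_perm` remains 1,000 for real use.

## Known limitations

* The chance model and the screen are tied to the binomial coin-flip
  convention; under class imbalance the majority-class accuracy (0.609 for
  53/87) exceeds the 0.59 threshold, so the AUC floor is load-bearing.
* The t-test variant of the permutation p is reported for completeness but
  should not be used for inference.
* With several true regions in one tract, the 10-node RFE budget splits
  between them; per-region selection frequencies drop and a single cohort
  typically resolves one of the regions more sharply than the others.
* No multiple-testing correction is applied across the 80 tract/property
  screens (by design of the screening stage); the permutation tests guard
  the survivors individually.
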