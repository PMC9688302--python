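# Methods

`voxelage` implements an interpretable brain-age analysis: a tree-ensemble
regression of chronological age on voxel-wise gray-matter volume (GMV),
decomposed per subject into exact Shapley values and pairwise Shapley
interactions, with the interactions treated as per-subject brain networks
that are compared across the cohort through an affine-invariant metric on
symmetric positive-definite (SPD) matrices.

## Regression model

Age is modeled as `y = f(x) + e` with `x` the vector of selected GMV
features and `f` a gradient-boosted ensemble of depth-limited regression
trees (XGBoost), `f(x) = b + Σ_k t_k(x)`.  The fitted booster is exported
into an explicit tree representation (split feature, threshold, per-node
training cover, leaf value) and everything downstream consumes only that
export.  Splits follow the convention *left iff `x[feature] < threshold`*,
with feature values compared in float32 as the library does.  Export
fidelity is asserted at fit time: mirroring the library's float32
accumulation reproduces its predictions bitwise; the package's canonical
float64 predictions differ from the library's only by float32 summation
error (~1e-5 on age-scale outputs) and are what the Shapley identities
reproduce exactly.

Default hyperparameters: depth 4, 200 rounds, learning rate 0.1,
`colsample_bytree` 0.5, no row subsampling, single-threaded and seeded.
Depth is limited for two reasons: it regularizes the fit on strongly
correlated voxel features, and it bounds the number of distinct features
per tree, which the interaction engine depends on.  Per-tree feature
subsampling matters qualitatively, not just as regularization: voxel
features are highly redundant, and with all features available in every
tree, greedy split selection can ignore a voxel pair's *joint* signal
entirely (some correlated voxel always offers more immediate univariate
gain, so the pair's two voxels never co-occur in a tree and their
interaction is identically zero).  Sampling half the features per tree
forces trees into contexts where the joint readout is the best available
split, letting the ensemble express interactions that are genuinely in the
data.

## Feature preparation

Inputs are spatially normalized GMV maps (the package assumes segmentation
and registration have already been done).  Three deterministic steps:
Gaussian smoothing at a configurable FWHM (`sigma = FWHM / (2 sqrt(2 ln 2))`
per axis, mask-renormalized to avoid edge attenuation), an unsupervised
variance filter (sample variance strictly greater than the threshold,
unbiased estimator), and univariate F-test selection of the top-k voxels by
`F = r² (N−2) / (1 − r²)` with `r` the Pearson correlation with age (ties
broken by ascending voxel index; zero-variance columns get F = 0 with a
warning).  Full-scale defaults mirror common VBM practice (FWHM 6 mm,
variance threshold 0.01, k = 2000); the desk-scale preset (no additional
smoothing, threshold 1e-4, k = 50) is matched to the synthetic cohort,
whose volumes are generated already spatially smooth on a [0, 1]
tissue-probability-like value scale where a 0.01 variance cut would be
off-scale.

## Shapley decomposition

For one subject, the prediction decomposes as `y = φ0 + Σ_i φ_i` where
`φ_i` is the Shapley value of feature i under the coalition game
`f(S)` = the tree-ensemble expectation with only the features in S known:
at a split on a feature in S the subject's branch is followed, otherwise
both children are averaged with training-cover weights (the path-dependent
tree-conditional expectation).  `φ0 = f(∅)` is the cover-weighted mean
prediction — the model baseline, numerically close to the mean training
age for a squared-error booster whose base score is set to it.

Pairwise synergy uses the Shapley interaction index

    φ_ij = Σ_{S ∌ i,j} |S|!(M−|S|−2)! / (2(M−1)!) · δ_ij(S),
    δ_ij(S) = f(S∪{i,j}) − f(S∪{i}) − f(S∪{j}) + f(S),

with the diagonal defined as the main effect net of interactions,
`φ_ii = φ_i − Σ_{j≠i} φ_ij`.  Three identities hold by construction and
are enforced as contracts (tolerances 1e-8 absolute on an age scale,
1e-10 for the row identity): additivity `φ0 + Σφ_i = y`, completeness
`Σ_i Σ_j φ_ij = y − φ0`, and row consistency `φ_i = φ_ii + Σ_{j≠i} φ_ij`.
Note the completeness identity sums to the prediction *minus the baseline*;
summing to the raw prediction would contradict additivity plus the
diagonal definition.

Two independent implementations exist.  The brute-force oracle enumerates
all 2^M subsets with explicit factorial weights (capped at M = 15).  The
production engine exploits that a tree's conditional expectation depends
only on the features the tree actually splits on, so all other features
are Shapley dummies and the ensemble decomposition is the sum of exact
per-tree decompositions over each tree's small support (u ≤ 2^depth − 1
features, 2^u-entry game tables, batched over subjects with precomputed
weight matrices).  This is exact, not approximate: agreement with the
oracle is at machine precision, and the 1e-6 equivalence tolerance in the
tests is pure slack.  Trees using more than 15 distinct features are
refused with a pointer to shallower depths.  An interventional
(background-sample) expectation is deliberately not implemented; the
path-dependent game is self-contained and deterministic.

## Voxel-level and network-level analyses

*Force view*: per subject, positive φ push the predicted age above the
baseline, negative φ pull it below; totals are over all features with a
truncated top-|φ| listing.  *Global importance*: mean |φ_i| over subjects;
the top-`n_peak_voxels` features are "peak voxels" (a selected voxel
stands in for its correlated neighborhood).  *Dynamics*: each subject's φ
vector is a point in R^M; classical (Torgerson) MDS on pairwise Euclidean
distances — double-center the squared distances, eigendecompose, scale the
top eigenvectors by sqrt of the non-negative-clamped eigenvalues, fix the
sign of each axis so its first nonzero loading is positive — yields a 2D
embedding annotated with age, sex, and dementia level.  MDS on genuinely
Euclidean input reproduces the distances exactly; negative eigenvalues
(non-Euclidean input) are clamped with a logged warning.

For networks, each subject's interaction matrix (restricted to the peak
voxels; the full-feature matrix is quadratic in memory and the peak
voxels carry the signal) is the weighted adjacency of their voxel
network.  The regularized graph Laplacian `Ā = (D − W) + λI` maps it to
an SPD matrix; by default edge weights are |φ_ij| (a signed Laplacian can
be indefinite; signed mode exists behind a flag with an explicit
positive-definiteness check) and the adjacency diagonal is zeroed so the
comparison reflects interactions only.  λ defaults to 1.0 — no principled
value exists for it, so the pipeline logs a sensitivity check: the Spearman rank correlation of the cohort distance matrix at λ/10
and 10λ against λ (typically > 0.9, i.e. the orderings it feeds are
stable).  Subjects are compared with the affine-invariant SPD distance
`d²(P, Q) = Σ_k log² λ_k(Q, P)` (generalized eigenvalues; equal to
`tr log²(P^{-1/2} Q P^{-1/2})`, and an explicit matrix-log route is kept
as an internal cross-check).  The squared form is what the defining trace
formula yields; the square root is the proper metric and is what
thresholding and embedding use.  The cohort "network of networks" retains
the `keep_fraction` (default 25%) smallest pairwise distances as edges,
ties broken by ascending index pair.

## Synthetic cohort

The generator emulates the structure of a cross-sectional aging cohort
(default 403 subjects aged 18–96, ~60% female, a 4-level dementia rating
assigned only above age 60) on a small 3D grid with a [0, 1]
tissue-probability-like GMV scale (baseline 0.6).  Ages are uniform by
default (a bimodal option mirrors convenience-cohort histograms; uniform
maximizes identifiability for recovery tests).  Noise is white Gaussian,
spatially smoothed (default FWHM 4 mm) and rescaled to a per-voxel sd of
`noise_sd`, emulating the neighbor correlation of VBM maps.  Values are
clipped at zero after all contributions.

Planted structure:

* **Main effects** — `n_informative` voxels with GMV affine in age
  (default slopes −0.002 to −0.006 per year: with noise sd 0.05 these give
  single-voxel age correlations of ~0.67–0.94).  With zero noise and no
  interactions the planted voxels are exactly affine in age.
* **Interactions** — *lateralized staged atrophy*.  For a planted pair,
  each subject loses GMV in one of the two voxels (a random side), by
  `0.15 · strength · g` where `g` ramps over the pair's age window; with
  several pairs the windows partition the age range (staged progression),
  so pairs are not redundant with one another.  Each pair voxel has a real
  marginal age effect (univariate screening keeps it; tree splits on it
  carry gain), but a near-baseline value is ambiguous — young, or
  atrophied on the other side — and is resolved only jointly, which is
  exactly the structure the Shapley interaction index rewards.  A design
  worth recording: a "pure" interaction whose carrier sign has no marginal
  effect is statistically clean but *undiscoverable by greedy boosting*
  (no split on the carrier ever has first-order gain), and a construction
  whose interactions touch only an unobserved latent never reaches the
  observed data at all; lateralized atrophy avoids both failure modes and
  has a biological reading (asymmetric neurodegeneration).

What the generator does *not* emulate: scanner artifacts, registration
error, longitudinal structure, realistic anatomical covariance, or the
empirical GMV value distribution after DARTEL — passing recovery tests
shows the method recovers planted structure under controlled conditions,
not that it would behave identically on real scans.

## The frozen recovery benchmark

`recovery_benchmark_spec`: 300 subjects, 12³ grid (2 mm voxels), 20
main-effect voxels with *equal* slopes of −0.0015/yr (single-voxel r ≈
0.56), two lateralized pairs at strength 3 (atrophy depth 0.45 on the 0.6
baseline across each pair's window), noise sd 0.05.  Equal weak slopes are
deliberate twice over: no voxel comes close to determining age alone
(test MAE lands in the mid single digits of years, in the range reported
for whole-brain GMV age prediction rather than an unrealistically clean
fit), and no dominant voxel floods the interaction ranking — for two
redundant informative voxels `δ_ij(S) ≈ −(main effect)` whenever S already
contains neither, so redundancy-driven |φ_ij| scales with the largest
importances and would otherwise bury any planted synergy.  These
conditions and the associated test margins were fixed after a single
calibration pass and are not revisited.

Desk-scale problem sizes throughout (50 selected features, 20 peak
voxels, 300 subjects) keep the full pipeline — generation, preprocessing,
fitting, exact values *and* interactions for every subject, networks, and
the cohort distance matrix — at around a minute single-threaded.

## Numerical conventions

* All randomness flows from explicit seeds; one root seed fans out to
  per-stage child seeds (below 2³¹), and fitting is single-threaded, so a
  pipeline run is byte-reproducible.
* Ranking operations (peak voxels, displayed edges, retained
  network-of-network edges) sort by value with ties broken by ascending
  index, so outputs are order-stable.
* Edge counts from a retention fraction are `round(fraction · n_pairs)`,
  at least 1.
* Degenerate inputs error early with the offending field or subject named:
  empty cohorts, mismatched grids, non-finite voxels, asymmetric
  dissimilarities, non-PD inputs to the geodesic, zero covers in a tree.

## Known limitations

* The Shapley game is path-dependent (cover-weighted); interventional
  expectations against a background sample are a different estimand and
  are out of scope.
* Exact interaction cost grows as 2^u per tree; depth ≤ 4 is comfortable,
  very deep trees are refused rather than approximated.
* The interaction stage materializes an M×M matrix per subject chunk;
  at M = 2000 this is transient ~32 MB per subject, so cohort-scale
  interaction analyses are meant to run on the peak-voxel subset.
* Real-data mode expects already-normalized GMV NIfTI volumes plus a
  metadata table; no segmentation, registration, or quality control is
  provided.
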