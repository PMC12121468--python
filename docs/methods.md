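# Methods

This note documents the models, algorithms and design choices behind
`astromorph`, in the order the pipeline runs them.

## Skeletons and validation

A skeleton is a rooted tree of nodes `(id, type, x, y, z, radius, parent)`
in classic 7-column SWC, coordinates in micrometres (no unit conversion is
attempted). Validation enforces: unique ids, strictly positive radii,
exactly one root (`parent = -1`), a soma-typed (type 1) root, all parents
present, and acyclicity; nodes are re-ordered topologically on load, so
downstream code can always assume parent-before-child. Multi-node somas
(several contiguous type-1 nodes) are accepted; the root node is the soma
centre. Writing renumbers ids 1..N and uses `repr` float formatting, which
makes write → read → write byte-identical. One SWC file is one astrocyte;
cells are never pooled across files.

## Sholl analysis

Intersections are counted between process segments (straight edges between
consecutive nodes; soma–soma edges excluded) and concentric spheres of
radius k·step (step = 1 µm by default) centred on the soma root.
Each segment is intersected with each sphere *exactly*: the distance-to-
centre function along a straight segment is unimodal, so the segment is
split at its point of closest approach into at most two monotone runs, and
a run spanning distances (a, b] contributes one crossing for every integer
rank a < k·step ≤ b. The half-open convention makes a sphere that passes
exactly through a node count once, deterministically. For radially
monotone segments this is the familiar endpoint rule (one crossing when
min(d) < r ≤ max(d)); for near-tangential segments whose interior dips
below a sphere that both endpoints clear, it correctly counts two
crossings. The test suite verifies exact agreement, on every radius, with
an oracle that resamples every edge at 0.001 µm arc-length.

The curve ends at R_max, the largest radius with a non-zero count. The
Sholl median is taken over radii 1..R_max inclusive (zeros inside the
support count, zeros beyond do not); peak ties break toward the smallest
radius. The number of primary branches is defined as the Sholl count at
radius 1 µm — the intersection-profile estimate, not a count of soma
children — and the ramification index is peak count / primary count,
reported as missing (NaN) when the primary count is zero. Cells with a
missing ramification index are dropped before scaling, with a logged count.

## Branch decomposition

A branch is a maximal edge path between consecutive topological nodes
(soma, branching points with ≥ 2 children, terminals). Branch depth is the
number of branching points strictly between the soma and the branch's
start; level = depth + 1. The soma is never a branching point, however
many primary processes it bears, and branch length includes the attachment
edge from the soma node to the first process node. Per-cell summaries take
the median over branches (depth, level) or totals (counts, length).

## Scaling and component retention

Features are z-scored column-wise (n−1 standard deviation; constant
columns are an error naming the feature). The branching features are
heavily right-skewed — they span about two decades across morphotypes — so
by default the strictly positive ones (total process length, branch count,
Sholl peak, primary count, ramification index) are log10-transformed
before scaling and the counts that can be zero (branching points, Sholl
median, branch depth/level medians) use log10(1 + x). Both lists are
configurable (`features.log10`, `features.log10p`); soma diameter stays on
its natural scale. Without this treatment the most complex cells dominate
the correlation structure and the z-scale compresses the separation
between the simpler morphotypes.

PCA is the eigendecomposition of the correlation matrix (equivalently,
PCA of the z-scores); eigenvalues therefore sum to the number of features,
and loading signs are fixed so each column's largest-magnitude entry is
positive. Retention combines two criteria as a conjunction, each a leading
run: Kaiser (eigenvalue strictly > 1) and Horn's parallel analysis
(eigenvalue above the per-rank 95th percentile — configurable, mean
thresholding available — of eigenvalues from `n_iter` = 1000 simulated
standard-normal datasets of the same shape). The retained count is the
minimum of the two leading runs; a floor of 2 components
(`pca.min_components`) keeps clustering viable when only one component
passes, and a zero result without a floor is an error.

## Clustering and model selection

Clustering operates on the retained PC scores only, Euclidean metric
throughout. Four algorithms are fitted: agglomerative hierarchical
clustering (Ward linkage by default, configurable; scipy linkage),
best-of-25-restarts k-means (scikit-learn), PAM implemented in-package
(greedy BUILD, then steepest-descent SWAP over all medoid/non-medoid
exchanges until no improvement), and an online 1-D self-organizing map
implemented in-package (k×1 grid, Gaussian neighbourhood and learning rate
decaying linearly; with the neighbourhood forced to zero the update is
online k-means).

The number of clusters is a majority vote of eight internal indices over
`k_range` (default 2..8), computed on hierarchical labels:
Calinski–Harabasz, mean silhouette, Dunn, Davies–Bouldin, the gap
statistic (50 uniform feature-range reference sets; smallest k with
Gap(k) ≥ Gap(k+1) − s(k+1)), Hartigan's rule (smallest k with
H(k) ≤ 10), the C-index and Krzanowski–Lai. Ties break toward smaller k
(parsimony); an all-way tie falls back to the silhouette's k with a
warning. This defined panel stands in for the much larger index
collections in common use; it is configurable (`cluster.panel`). The
algorithm is then selected at the chosen k by the mean standardized score
of connectivity (negated; 10 nearest neighbours), Dunn and silhouette —
the internal-validation triple — across candidates.

Degenerate cases are defined, not errors: a singleton cluster's silhouette
is 0, and a partition with zero maximum intra-cluster diameter has Dunn 0
(flagged).

## DAPC

The discriminant analysis of principal components solves the
between/within scatter generalized eigenproblem on the retained PC scores
with the cluster labels, keeping k − 1 axes normalised in the within-class
metric (aᵀS_w a = 1, signs fixed for determinism; a 1e-8 ridge is added and
logged if S_w is singular). In that space the shared within-class
covariance is the identity, so posteriors with uniform priors are a
softmax of −½ × squared distance to class centroids; with k = 2 and all
dimensions kept this reproduces classic LDA posteriors exactly (tested
against scikit-learn). Refinement is one round of maximum-posterior
reassignment (iteration is deliberately off: repeated reassignment can
drift away from the clustering solution); a cluster emptied by
reassignment keeps its highest-posterior cell, with a warning. All PCs
passed in are used — the PC choice was already fixed upstream.

The variable contribution filter defines the contribution of a feature to
a cluster as the absolute mean of its z-scores within that cluster; a
feature is kept for cluster characterisation iff its maximum contribution
exceeds 0.7 *and* a Kruskal–Wallis test across clusters is significant at
0.05. The cluster-wise mean was chosen because the criterion is "in at
least one cluster", which is a per-cluster quantity; a discriminant-axis
loading variant would measure axis importance instead.

## Statistics

* **Kruskal–Wallis** (scipy, tie-corrected) with **Dunn's post hoc**:
  pairwise z statistics on pooled ranks with the pooled tie correction,
  two-sided normal p-values, Benjamini–Hochberg adjustment across all
  pairs of one family (one variable, one clustering).
* **Nested ANOVA**: genotype fixed, mouse random nested in genotype.
  Sequential sums of squares partition genotype / mouse-within-genotype /
  residual strata; the genotype F uses MS(mouse-within-genotype) as its
  denominator on (g − 1, m − g) degrees of freedom, so mice — not cells —
  are the replicates of genotype. This is the design reason for nesting:
  under a null with real mouse-to-mouse variance the genotype type-I error
  stays at ~5% where a cell-level one-way ANOVA is grossly anticonservative
  (both demonstrated in the test suite at 2000 Monte-Carlo reps).
  Unbalanced designs use the same group-size-weighted sequential SS, with a
  log note. At least two mice per genotype are required; one mouse per
  genotype makes genotype untestable and is an error.
* **Pearson χ²** on genotype × cluster tables (no continuity correction);
  zero-margin rows/columns are dropped with a warning and expected counts
  below 5 are flagged.
* **Sholl profile comparison**: curves are zero-padded to the cohort
  maximum radius (an absent process is a true zero intersection), an
  omnibus two-way ANOVA (genotype × radius) is fitted via statsmodels, and
  per-radius pooled-variance t contrasts are Bonferroni-corrected across
  radii at α = 0.01.
* **Complexity score**: per cluster, the mean z-score of branching-point
  count, branch count and ramification index; clusters are ranked low →
  high and labelled accordingly.
* Dunnett-style post hoc comparisons are approximated by Bonferroni
  contrasts (conservative) rather than the exact multivariate-t quantile.
* SEM is reported as sd/√n.

## Synthetic cohorts

The generator grows each cell as a stochastic branching process:
`max(2, Poisson(n_primary))` primaries leave the soma surface in
quasi-uniform (golden-spiral) directions; tips advance in 1 µm steps with
Gaussian angular jitter (`tortuosity`) and a configurable radial outward
bias (default 0.3, reflecting the radial organisation of protoplasmic
astrocyte processes — and keeping the branching process territory-limited);
every grown step carries bifurcation probability 1 − exp(−rate·step)
(a Poisson process in arc length, verified against the realised rate in
the tests); daughters diverge by ± a half-angle with jitter and draw fresh
exponential length budgets; growth stops at the territory radius or when
the budget is exhausted; radii taper outward with a 0.1 µm floor. Soma
size carries per-cell lognormal variability (sd 0.08 by default). A guard
raises before growth if the parameter combination implies an expected node
count beyond 10⁵.

Three archetypes — simple, medium, complex — are ordered in branch count,
branching-point count and ramification index. Their parameters are
stylised rather than fitted to any real dataset: gaps between classes are
spread over several semi-independent channels (soma size, territory
radius, bifurcation rate, primary count, tortuosity), and two channels are
deliberately non-monotone across the ordering (the medium archetype has
the most primaries and the most tortuous paths) so that the class
structure is two-dimensional in PC space rather than a single graded axis.
This makes the three morphotypes separable by design — the property the
clustering validation needs — while the within-class spread from the
branching process keeps the problem non-trivial (adjacent classes overlap
at roughly the 3–4 σ level on the leading components).

Default cohort design: 2 genotypes × 3 age groups × 3 mice × 3 subregions
× 15 cells = 810 cells, the scale of a full study census. Morphotype
mixtures per (genotype, age) follow the proportion structure reported for
wild-type vs tauopathy-model mice: an early-age excess of simple cells in
the transgenics, a mid-life medium/complex balance in wild-types against a
simplified transgenic profile, and a late-age complex subpopulation that
persists only in the transgenics. A per-mouse lognormal random effect
(sd 0.1) multiplies the bifurcation rate, giving the nested ANOVA a real
mouse stratum. What the generator does **not** emulate: leaflet-scale
nanomorphology, endfeet, self-avoidance or density-dependent growth,
absolute feature values of real astrocytes, or measurement noise from
imaging and tracing. Passing tests therefore demonstrate the correctness
and internal consistency of the analysis chain on data with known
structure — not that real cohorts contain three clusters.

## Determinism and numerics

A single master seed fans out to named substreams (simulation, Horn, k
selection, algorithm selection) via `SeedSequence` spawn keys, so the
pipeline is a pure function of (inputs, config, seed); reruns are
bitwise-identical including the JSON report. Tolerances: eigenvalue sum to
feature count 1e-8; DAPC posterior row sums 1e-9; isometry invariance of
features 1e-9 relative. PAM's SWAP accepts only improvements larger than
1e-12 to avoid cycling on ties; peak/vote ties break toward the smaller
radius/k.

Problem sizes in the shipped validation runs (100 skeletons for the Sholl
oracle, n = 300 for morphotype recovery, 360–810 cells for end-to-end
runs, 1000–2000 Monte-Carlo reps for the calibration checks) were chosen
as the smallest scales at which each property is statistically
informative; all scale up linearly via configuration.

## Known limitations

* The SWC reader does not repair broken trees or read Imaris exports.
* Soma diameter from SWC is 2 × root radius unless a measured value is
  supplied through the manifest; image-derived orthogonal-axis measures
  are not recoverable from skeletons.
* The Hartigan rule's fixed threshold (10) over-splits at large n; it is
  one vote among eight.
* The gap statistic uses feature-range uniform references (not
  PCA-aligned boxes).
* Horn's parallel analysis assumes approximately continuous features; with
  heavily tied discrete features its null is only approximate.
* The nested ANOVA uses the classical expected-mean-squares F test, not a
  REML mixed model; strongly unbalanced designs are handled by sequential
  SS, which is approximate.
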