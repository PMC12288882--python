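# Methods

This note documents the statistical model behind `declust`, the
parameter defaults and why they were chosen, what the synthetic data
emulate, and the numerical conventions that make runs reproducible.

## Model and assumptions

The central assumption is linear mixing: the (linear-scale) expression
of a spot is the sum of the expression of the cells it captures, so the
pseudo-bulk profile of a group of spots is approximately a non-negative
combination of cell-type mean profiles. Deconvolution at the level of
spatially coherent clusters rather than single spots trades spatial
granularity for signal strength: per-spot Visium counts are sparse
enough that spot-wise regression is noise-dominated, while cluster
pseudo-bulk aggregates tens to hundreds of spots.

Three further assumptions are implicit and worth stating:

* the scRNA-seq reference contains every cell type present in the
  tissue (types absent from the reference are unidentifiable);
* within a cluster, spot composition is roughly constant — the
  cluster-level proportion vector is broadcast unchanged to member
  spots, so within-cluster composition gradients are smoothed away;
* marker genes behave multiplicatively alike in ST and scRNA-seq data
  (no platform effect correction is applied).

## Stage 1 — spatial clustering

**Hierarchical stage.** Spots are clustered on log1p library-size
normalized expression (library size scaled to 10⁴) over the shared
variable-gene space, with Ward linkage on Euclidean distance. The
cluster count h is selected on the within-cluster sum of squares curve
computed from a single Ward tree (so the partitions are nested and the
curve provably non-increasing). The elbow is automated as the h
maximizing the discrete second difference of the curve over a
configurable range (default 2–15; a flat curve falls back to the range
minimum). An automated criterion was needed because a visual elbow is
not reproducible in a CLI; the second difference is the discrete
curvature, which is the quantity the visual heuristic tracks.

**DBSCAN stage.** Within each expression cluster, DBSCAN runs on spot
coordinates with ε = 4 and minPts = 8 *in array-grid units* — this is
why the readers use the integer `array_row`/`array_col` of the Visium
positions table as the coordinate system rather than pixels. Spots
unreachable at that density become NOISE and are deliberately left
unlabeled for the region-growing stage to re-assign.

**Seeds.** Sub-clusters holding < 5% of all spots in the dataset
contribute no seeds (the fraction is measured against the whole dataset,
not the parent cluster). From larger sub-clusters, ⌊0.5 × eligible⌋
interior spots are drawn uniformly without replacement. "Interior"
means having a full complement of spatial neighbours; a spot with fewer
is a tissue-boundary spot and never seeds. Rounding is down.

**Spatial neighbours.** A spot's neighbours are its 8 nearest spots by
Euclidean coordinate distance within a radius of 2 grid units. On a
square lattice this is exactly the 8-neighbourhood; on the hex-packed
Visium grid (where row-adjacent spots sit at distance √2 and
column-adjacent at distance 2) it captures the physically adjacent ring.
Both k and the radius are configurable.

**Seeded region growing.** A binary heap implements the sequentially
sorted list: it holds unlabeled spatial neighbours of the labelled
region keyed by (expression distance to the adjacent region's running
mean, spot index) — the index breaks ties deterministically. Popping
the minimum, the spot takes its neighbours' unanimous label if they
agree, otherwise the label of the expression-nearest adjacent region;
the region mean then updates incrementally. Keys are not re-sorted when
region means move (the classical formulation tolerates slightly stale
priorities; re-keying the whole frontier each iteration would be
quadratic). Spots in spatially disconnected islands that growth never
reaches are assigned post hoc to the expression-nearest region, with a
warning. Clusters ending below 3 spots are merged into their
expression-nearest cluster because near-empty pseudo-bulk rows make the
regression unstable. Final labels are renumbered 1..h by decreasing
size.

**Pseudo-bulk.** Cluster profiles are the *mean* (not sum) of member
spots' linear-scale expression, so cluster size does not scale the
regression response; since the estimator renormalizes each row, mean
and sum give identical proportions, but the mean keeps X\* on the same
scale as Ẑ for diagnostics. Configurable.

## Stage 2 — marker selection

Statistics are computed on log1p-normalized expression (heavy-tailed
counts behave badly in t-type statistics), while the reference matrix Ẑ
is built from *linear*-scale means, where the mixing model holds.

* **T1** is Welch's unequal-variance t-test of the target type's mean
  against the complement, one-sided (up-regulation), with
  Welch–Satterthwaite degrees of freedom. Group variances are floored
  at 1% of the gene's across-all-cells variance: dropout-heavy genes can
  have zero within-group variance, which would make the statistic
  infinite. The exact "robust" variant is an open design point; Welch
  with a floor is deterministic, robust to unequal group sizes, and the
  choice is recorded in output metadata.
* **T2** is a Cochran's-Q-style heterogeneity chi-square across the
  non-target types: Q = Σ_c w_c (m_c − m̄_w)² with w_c the inverse
  squared standard error of type c's mean, referred to χ² with
  (#remaining types − 1) df. Remaining types with < 2 cells are
  excluded with a df reduction. With only one remaining type (k = 2),
  homogeneity holds vacuously and T2 passes by construction.
* Genes pass with p(T1) < 0.05 and p(T2) > 0.05; per type the top 10
  passing genes by T1 are kept (ties broken by gene id). A type with no
  passing gene falls back to the top 10 by T1 alone, with a warning —
  an empty design-matrix row would abort the pipeline for every type.
  A gene may serve several types if it passes for each; the regression
  uses all Ẑ columns jointly, so exclusivity is not required.

Monte-Carlo calibration (run in the test suite) shows the joint
criterion's per-type false-pass rate tracks α1 closely (empirically
≈ 0.06 at nominal 0.05 on Poisson data), and each *true* marker
independently risks an ≈ α2-level chance rejection by T2 — recovery of
planted markers therefore concentrates around 1 − α2 ≈ 95%.

## Stage 3 — deconvolution

The estimator is exactly: unconstrained least squares per cluster,
negatives clipped to zero, row renormalized to sum one. It is
implemented through an SVD pseudo-inverse rather than the explicit
(ẐᵀẐ)⁻¹ for conditioning; the two agree to 1e-10 on well-conditioned
input (asserted in tests against an independent implementation of the
explicit formula). Clipping is *not* guaranteed to reach the true
non-negative least-squares optimum; `method="nnls"` provides a real
NNLS solver for comparison and is never silently substituted. Rows that
clip to all-zero degenerate to uniform proportions with a warning. A
rank-deficient Ẑ raises an error naming near-collinear cell-type pairs
(|r| > 0.999). Because each row is renormalized, the estimator is
invariant to positive rescaling of X\* — normalization differences
between ST data and reference cancel.

## Simulators and fixtures

**Multinomial mixture.** Per spot, cell-type counts are
Multinomial(10, proportions) — 10 cells per spot is in the plausible
range for Visium spot occupancy — then that many cells are drawn from
each type's reference pool and their linear counts summed. Sampling is
*with replacement*: rare types (a handful of cells) would otherwise
exhaust their pool; the choice is configurable. The recorded truth is
exactly counts/10, so truth rows carry multinomial sampling noise of
variance p(1−p)/10 around the target proportions — an irreducible floor
for any estimator that cannot see individual cells.

**LR enrichment.** To mimic co-localized interacting cell types, a
cluster can be enriched for a (ligand, receptor) gene pair: the
sampling pools for a named pair of cell types are restricted to cells
whose ligand AND receptor expression both reach the 0.75 quantile
(linear-interpolation quantile; ties pass via ≥). Cluster labels,
cluster-level proportions and LR pairs are *inputs* — the upstream
tools that would produce them on real data (spatial-domain detection,
bulk deconvolution, LR inference) are third-party and out of scope.

**Synthetic fixture.** `make_fixture` builds a k-type reference with
negative-binomial baseline counts (gamma–Poisson, log-normal per-gene
means, dispersion 0.5 — overdispersion typical of droplet scRNA-seq)
and 10 planted markers per type at 4-fold elevation, plus a square spot
lattice partitioned into contiguous domains (quadrants for k = 4).
Each domain's target proportion vector gives 0.8 to its own type and
splits the rest evenly. The 0.8 dominance reflects strongly organized
tissue (a cortical layer, a tumor bed) and keeps the multinomial truth
floor (mean over domains of p(1−p)/10 ≈ 0.009 per type) below the 0.01
per-type MSE the recovery tests demand — with weaker dominance the
floor alone exceeds that bound regardless of estimator quality.

What the fixture does *not* emulate: platform effects between ST and
reference, within-domain composition gradients, spatially varying
library size, segmentation artifacts at domain borders, and zero
inflation beyond NB. Passing recovery tests therefore demonstrates
correctness of the machinery under the stated generative model, not
performance on real tissue.

## Evaluation

Simulation accuracy: per-spot RMSE over cell types and per-type MSE
over spots (RMSE without the root), against realized truth. MSE is
pooled across replicate datasets when several are simulated.

Cross-validation for real data (no truth available): spots are dealt
round-robin into 10 folds within each cluster (clusters fixed from one
full-data run before CV — stratification "within clusters" presumes the
clusters are known), then a greedy swap pass exchanges same-cluster
spots between folds while it strictly reduces the count of same-fold
adjacent pairs. Perfect spatial non-adjacency is infeasible on dense
lattices, so the residual violation count is reported instead of
pretended away. Test-spot proportions are the renormalized mean of
neighbouring training spots (nearest training spot as fallback);
expression is reconstructed as the proportion-weighted sum of cell-type
mean profiles; and per-spot RMSE, Pearson correlation, and the
rank-difference Spearman formula (1 − 6Σd²/(g(g²−1)), midranks under
ties — exact Spearman only on tie-free data, documented) score the
reconstruction. Metrics are computed on log1p library-size-normalized
observed and reconstructed profiles over the marker-gene space: the
reconstruction lives on the reference's per-cell scale while observed
spots hold ~10 cells' counts, so a common normalization is required for
RMSE to be meaningful; correlations are unaffected by the choice.
Constant rows yield undefined correlations, recorded as missing and
excluded from medians with a warning.

The training stage of each fold runs the full pipeline on training
spots only; a leakage test asserts that perturbing test-spot expression
leaves every training artifact byte-identical (fold assignment held
fixed — the stratifying cluster labels necessarily derive from all
spots).

## Reproducibility and problem sizes

A single run seed fans out to per-stage child seeds via
`numpy.random.SeedSequence.spawn` in a fixed stage order, so stages are
independently reproducible and reruns are byte-identical. All ranking
ties (variable genes, markers, SRG frontier, cluster renumbering) break
by identifier or index.

The validation suite runs entirely on synthetic data: recovery checks
use a 20×20-lattice fixture (400 spots, 200 genes, 4 types, 50
cells/type, 3 replicates) and marker calibration uses 400–1000 genes —
sizes at which every property under test is already well-resolved while
the whole suite completes in seconds.

## Known limitations

* Within-cluster composition is constant by construction; gradients and
  rare infiltrating cells inside a domain are invisible.
* Clipped OLS is a heuristic projection onto the simplex; in
  ill-conditioned designs it can differ from true NNLS (the NNLS flag
  exists for exactly this diagnosis).
* The elbow criterion can pick a shallow elbow on weakly structured
  tissue; `n_clusters` in the config overrides it.
* DBSCAN's ε = 4 / minPts = 8 presume Visium-like array geometry; other
  platforms need re-tuning (both are exposed).
* Cell types absent from the reference are silently absorbed into the
  proportions of present types.
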