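# declust

Cluster-based cell-type deconvolution of spatial transcriptomics (ST) data.

Array-based ST platforms such as 10x Visium measure transcriptome-wide
expression at barcoded spots, but each spot mixes mRNA from several cells
of different types, and per-spot counts are sparse. `declust` estimates
the cell-type composition of every spot by deconvolving *aggregated*
expression of spatially coherent spot clusters rather than individual
spots, which strengthens the signal while preserving tissue structure.
It is aimed at computational biologists analysing Visium-style ST data
with a matched annotated scRNA-seq reference.

## Method

Given an ST expression matrix *X* (*n* spots × genes) with 2D spot
coordinates and a reference *Z* (*m* cells × genes) with *k* cell-type
labels:

1. **Spatial clustering.** The top 5000 most variable genes shared by
   both datasets are kept. Spots are clustered on expression by
   Ward-linkage hierarchical clustering, the cluster count chosen at the
   elbow of the WCSS curve, WCSS = Σ_j Σ_i ‖x_i⁽ʲ⁾ − μ_j‖². DBSCAN
   (ε = 4, minPts = 8, array-grid units) carves each expression cluster
   into dense spatial sub-clusters; 50% of the interior spots of every
   sub-cluster holding ≥ 5% of all spots are sampled as seeds; and a
   seeded region growing pass assigns every spot to a region via a
   sequentially sorted list keyed by expression distance to the running
   region means. Each final cluster is aggregated into a pseudo-bulk
   profile, giving *X\** (*h* clusters × genes).
2. **Marker selection.** For each cell type, a one-sided robust t-test
   (T1) finds genes up-regulated in that type versus all others, and a
   heterogeneity chi-square (T2) checks that the remaining types express
   the gene homogeneously. Genes with p(T1) < 0.05 and p(T2) > 0.05 are
   ranked by T1 and the top t = 10 per type retained; the reference
   matrix Ẑ (*k* × markers) holds each type's mean expression.
3. **Deconvolution.** Per cluster, Y[i] = (ẐᵀẐ)⁻¹Ẑᵀ X\*[i]; negative
   coefficients are clipped to zero and the row renormalized so that
   Σ_j Y_ij = 1, Y_ij ≥ 0. Cluster proportions are broadcast to member
   spots, giving Ŷ (*n* × *k*).

The package also ships the evaluation machinery: multinomial mixture
simulators (10 cells per spot, optionally with ligand–receptor co-enriched
clusters), RMSE/MSE proportion metrics, and a spatially stratified
10-fold cross-validation that predicts held-out spots from their
neighbours and scores the reconstructed expression by RMSE, Pearson and
Spearman correlation.

## Worked example

Everything runs on synthetic data; no downloads are needed.

```sh
declust fixture --preset small --rng-seed 1 --out-dir fixture
declust run --st-expr fixture/st_expr.csv --st-coords fixture/st_coords.csv \
    --sc-expr fixture/sc_expr.csv --sc-labels fixture/sc_labels.csv \
    --rng-seed 1 --out-dir out
declust evaluate --mode sim --truth fixture/truth.csv \
    --pred out/proportions_spot.csv
```

which prints:

```
wrote fixture (small) to fixture
wrote pipeline outputs to out (4 clusters, 40 markers)
overall RMSE: 0.0895
MSE[type_0]: 0.00957
MSE[type_1]: 0.00936
MSE[type_2]: 0.01103
MSE[type_3]: 0.00938
```

The fixture is a 10×10 spot lattice with four contiguous domains, each
dominated (80%) by one of four cell types, simulated at 10 cells per
spot. The pipeline recovers the four domains and 10 markers per type;
per-spot RMSE of 0.09 and per-type MSE near 0.01 are close to the
irreducible multinomial sampling noise of the 10-cell spots, i.e. the
estimator is about as accurate as the ground truth's own granularity
allows. `out/proportions_spot.csv` holds the spot-level proportions
(rows sum to 1); `out/manifest.json` records the config, input checksums
and versions needed to reproduce the run.

The same pipeline is exposed as a library:

```python
import declust

sc_ref, sim, domains = declust.make_fixture(n_spots=400, rng_seed=1)
res = declust.run_pipeline(sim.st, sc_ref, declust.RunConfig(rng_seed=1))
res.spot_props.to_frame().head()
```

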