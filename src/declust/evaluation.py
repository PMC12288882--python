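"""Simulation metrics and the spatial cross-validation harness.

Simulation accuracy is scored as per-spot RMSE over cell types and
per-type MSE over spots, against the realized truth matrix S.

For real data, where truth is unavailable, a 10-fold spatial
cross-validation exploits the strong correlation between neighbouring
spots: folds are stratified within spatial clusters and de-adjacencified
best-effort; each test spot's proportions are predicted as the average
of its training neighbours; the proportions are convolved with the
cell-type mean profiles to reconstruct the spot's expression; and the
reconstruction is scored against the observed expression per spot by
RMSE, Pearson correlation and a rank-difference Spearman coefficient
(midranks under ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .deconvolution import ProportionMatrix
from .spatial_clustering import spatial_neighbors

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    fold_of: np.ndarray          # per-spot fold id, 1..F
    n_folds: int
    adjacency_violations: int    # residual same-fold adjacent pairs


@dataclass
class CVReport:
    per_spot: pd.DataFrame       # spot_id, fold, rmse, pcc, scc
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# simulation metrics
# ---------------------------------------------------------------------------

def _align(Y_hat, S):
    a = Y_hat.values if isinstance(Y_hat, ProportionMatrix) else np.asarray(Y_hat, float)
    b = S.values if isinstance(S, ProportionMatrix) else np.asarray(S, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if isinstance(Y_hat, ProportionMatrix) and isinstance(S, ProportionMatrix):
        if Y_hat.cell_type_order != S.cell_type_order:
            order = [Y_hat.cell_type_order.index(t) for t in S.cell_type_order]
            a = a[:, order]
    return a, b


def proportions_rmse(Y_hat, S):
    """Per-spot RMSE over cell types, and the overall mean.

    ``rmse_i = sqrt(mean_j (Ŷ_ij − S_ij)²)``.
    """
    a, b = _align(Y_hat, S)
    per_spot = np.sqrt(((a - b) ** 2).mean(axis=1))
    return per_spot, float(per_spot.mean())


def mse_by_type(Y_hat, S):
    """Per-cell-type MSE averaged over spots (RMSE without the root)."""
    a, b = _align(Y_hat, S)
    return ((a - b) ** 2).mean(axis=0)


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def _count_violations(fold_of, nbrs):
    v = 0
    for i, row in enumerate(nbrs):
        for j in row:
            if j > i and fold_of[i] == fold_of[j]:
                v += 1
    return v


def make_folds(final_labels, coords, F: int = 10, rng_seed: int = 0,
               neighbor_k: int = 8, neighbor_radius: float = 2.0,
               max_passes: int = 3) -> FoldAssignment:
    """Cluster-stratified folds with best-effort spatial non-adjacency.

    Within each cluster, spots are shuffled (seeded) and dealt
    round-robin over folds; a greedy swap pass then exchanges spots
    between folds (within the same cluster) whenever the exchange
    strictly reduces the count of same-fold adjacent pairs.  Perfect
    non-adjacency is not always feasible; the residual count is reported.
    """
    if F < 2:
        raise ValueError("need F ≥ 2")
    final_labels = np.asarray(final_labels)
    n = final_labels.shape[0]
    rng = np.random.default_rng(rng_seed)
    fold_of = np.zeros(n, dtype=int)
    for c in np.unique(final_labels):
        members = np.flatnonzero(final_labels == c)
        perm = rng.permutation(members)
        for pos, spot in enumerate(perm):
            fold_of[spot] = pos % F + 1

    nbrs = spatial_neighbors(coords, k=neighbor_k, radius=neighbor_radius)

    def local_viol(i, fold):
        return sum(1 for j in nbrs[i] if fold_of[j] == fold and j != i)

    for _ in range(max_passes):
        improved = False
        for i in range(n):
            cur = local_viol(i, fold_of[i])
            if cur == 0:
                continue
            # try swapping i with a same-cluster spot in another fold
            for j in np.flatnonzero(final_labels == final_labels[i]):
                if fold_of[j] == fold_of[i]:
                    continue
                before = cur + local_viol(j, fold_of[j])
                fi, fj = fold_of[i], fold_of[j]
                fold_of[i], fold_of[j] = fj, fi
                after = local_viol(i, fj) + local_viol(j, fi)
                if after < before:
                    improved = True
                    break
                fold_of[i], fold_of[j] = fi, fj
        if not improved:
            break
    return FoldAssignment(fold_of=fold_of, n_folds=F,
                          adjacency_violations=_count_violations(fold_of, nbrs))


# ---------------------------------------------------------------------------
# prediction, reconstruction, scoring
# ---------------------------------------------------------------------------

def neighbor_average_predict(Y_hat_train: ProportionMatrix, coords, train_index,
                             test_index, neighbor_k: int = 8,
                             neighbor_radius: float = 2.0) -> np.ndarray:
    """Test-spot proportions as the mean of neighbouring training spots.

    ``train_index``/``test_index`` are integer positions into ``coords``;
    rows of ``Y_hat_train`` align with ``train_index``.  Test spots with
    no training neighbour fall back to the nearest training spot
    (warning).  Rows are renormalized to sum to one.
    """
    coords = np.asarray(coords, dtype=float)
    train_index = np.asarray(train_index)
    test_index = np.asarray(test_index)
    vals = Y_hat_train.values if isinstance(Y_hat_train, ProportionMatrix) \
        else np.asarray(Y_hat_train, float)
    row_of = {int(s): i for i, s in enumerate(train_index)}
    nbrs = spatial_neighbors(coords, k=neighbor_k, radius=neighbor_radius)
    out = np.zeros((len(test_index), vals.shape[1]))
    fallbacks = 0
    for r, s in enumerate(test_index):
        rows = [row_of[j] for j in nbrs[s] if j in row_of]
        if not rows:
            fallbacks += 1
            d = np.linalg.norm(coords[train_index] - coords[s], axis=1)
            rows = [int(np.argmin(d))]
        pred = vals[rows].mean(axis=0)
        out[r] = pred / pred.sum()
    if fallbacks:
        logger.warning("%d test spot(s) had no training neighbour; "
                       "used nearest training spot", fallbacks)
    return out


def convolve_expression(Y_row, sc_ref, genes=None) -> np.ndarray:
    """Reconstruct a spot profile as the proportion-weighted sum of
    cell-type mean expression profiles (all reference cells, linear scale)."""
    Y_row = np.asarray(Y_row, dtype=float)
    if not np.isclose(Y_row.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    ref = sc_ref if genes is None else sc_ref.subset_genes(genes)
    means = np.vstack([ref.expr[ref.cells_of_type(ct)].mean(axis=0)
                       for ct in ref.type_order])
    return Y_row @ means


def _spearman_rank_formula(x, y):
    """1 − 6 Σd² / (g(g²−1)) with midranks; exact Spearman when tie-free."""
    g = len(x)
    rx, ry = rankdata(x), rankdata(y)
    return 1.0 - 6.0 * float(((rx - ry) ** 2).sum()) / (g * (g ** 2 - 1))


def cv_metrics(observed: np.ndarray, predicted: np.ndarray,
               spot_ids=None, folds=None) -> CVReport:
    """Per-spot RMSE / Pearson / Spearman of reconstructed expression.

    ``observed`` and ``predicted`` are aligned spot × gene matrices.
    Spots with a constant observed or predicted row have undefined
    correlations; they are recorded as NaN and excluded from the medians.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted shapes differ")
    n, g = obs.shape
    if g < 2:
        raise ValueError("need at least 2 genes")
    rows = []
    for i in range(n):
        o, p = obs[i], pred[i]
        rmse = float(np.sqrt(((o - p) ** 2).mean()))
        so, sp = o.std(), p.std()
        if so == 0 or sp == 0:
            pcc = scc = np.nan
        else:
            pcc = float(np.corrcoef(o, p)[0, 1])
            scc = _spearman_rank_formula(o, p)
        rows.append((spot_ids[i] if spot_ids is not None else i,
                     folds[i] if folds is not None else 0, rmse, pcc, scc))
    df = pd.DataFrame(rows, columns=["spot_id", "fold", "rmse", "pcc", "scc"])
    n_und = int(df.pcc.isna().sum())
    if n_und:
        logger.warning("%d spot(s) with undefined correlation excluded from medians",
                       n_und)
    summary = {
        "median_rmse": float(df.rmse.median()),
        "median_pcc": float(df.pcc.median(skipna=True)),
        "median_scc": float(df.scc.median(skipna=True)),
        "mean_rmse": float(df.rmse.mean()),
        "n_spots": n,
    }
    return CVReport(per_spot=df, summary=summary)


# ---------------------------------------------------------------------------
# the harness
# ---------------------------------------------------------------------------

def cv_fold_train(st, sc, train_positions, config):
    """Training stage for one fold: the full pipeline on training spots only.

    Exposed separately so that the no-leakage contract (training
    artifacts independent of test-spot expression) is directly checkable.
    """
    from .deconvolution import run_pipeline

    train_st = st.subset_spots(np.asarray(train_positions))
    return run_pipeline(train_st, sc, config)


def run_cv(st, sc, pipeline_config=None, F: int = 10, rng_seed: int = 0,
           metric_genes: str = "markers") -> CVReport:
    """Spatial 10-fold cross-validation of the deconvolution pipeline.

    Cluster labels for fold stratification come from one full-data
    clustering run, fixed before CV.  Per fold, the pipeline runs on the
    training spots only; test-spot proportions are neighbour-averaged
    from training spots, convolved into expression, and scored against
    the observed expression.  Metrics are computed on log1p
    library-size-normalized profiles over the fold's marker-gene space
    (``metric_genes="shared"`` scores over all shared genes instead).
    """
    from .config import RunConfig
    from .io_model import normalize

    cfg = pipeline_config or RunConfig()
    full = None
    from .deconvolution import run_pipeline

    full = run_pipeline(st, sc, cfg)
    folds = make_folds(full.clustering.final_labels, st.coords, F=F,
                       rng_seed=rng_seed, neighbor_k=cfg.neighbor_k,
                       neighbor_radius=cfg.neighbor_radius)
    all_rows = []
    for f in range(1, F + 1):
        test_pos = np.flatnonzero(folds.fold_of == f)
        train_pos = np.flatnonzero(folds.fold_of != f)
        if test_pos.size == 0:
            continue
        try:
            fit = cv_fold_train(st, sc, train_pos, cfg)
        except Exception as exc:       # annotate with the fold index
            raise RuntimeError(f"fold {f} training failed: {exc}") from exc
        pred_props = neighbor_average_predict(
            fit.spot_props, st.coords, train_pos, test_pos,
            neighbor_k=cfg.neighbor_k, neighbor_radius=cfg.neighbor_radius)
        genes = fit.reference.marker_genes if metric_genes == "markers" \
            else fit.shared_genes.genes
        recon = np.vstack([convolve_expression(row, sc, genes=genes)
                           for row in pred_props])
        obs = st.subset_genes(genes).expr[test_pos]
        obs_n = normalize(obs, "cpm_log1p")
        rec_n = normalize(recon, "cpm_log1p")
        rep = cv_metrics(obs_n, rec_n,
                         spot_ids=[st.spot_ids[i] for i in test_pos],
                         folds=[f] * len(test_pos))
        all_rows.append(rep.per_spot)
    per_spot = pd.concat(all_rows, ignore_index=True)
    summary = {
        "median_rmse": float(per_spot.rmse.median()),
        "median_pcc": float(per_spot.pcc.median(skipna=True)),
        "median_scc": float(per_spot.scc.median(skipna=True)),
        "mean_rmse": float(per_spot.rmse.mean()),
        "n_spots": int(len(per_spot)),
        "adjacency_violations": folds.adjacency_violations,
    }
    return CVReport(per_spot=per_spot, summary=summary)
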