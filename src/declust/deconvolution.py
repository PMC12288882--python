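"""Non-negativity-constrained OLS deconvolution and spot expansion.

Each cluster's pseudo-bulk profile ``X*[i]`` is modelled as a linear
mixture of the cell-type reference profiles (rows of Ẑ).  The estimator
is literal: unconstrained least squares, negative coefficients clipped to
zero, then the row renormalized to sum to one.  Clipping is not
guaranteed to reach the true non-negative least-squares optimum; a real
NNLS solver is available behind ``method="nnls"`` for comparison and is
never silently substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

logger = logging.getLogger(__name__)


@dataclass
class ProportionMatrix:
    """Rows of cell-type proportions (cluster level Y or spot level Ŷ)."""

    values: np.ndarray
    row_ids: list
    cell_type_order: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.cell_type_order)):
            raise ValueError("shape does not match row/column ids")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("proportions must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.cell_type_order)


def _check_rank(Z: np.ndarray, cell_types) -> None:
    if np.linalg.matrix_rank(Z) < Z.shape[0]:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.nan_to_num(np.corrcoef(Z), nan=1.0)
        pairs = [
            (cell_types[i], cell_types[j])
            for i in range(len(cell_types))
            for j in range(i + 1, len(cell_types))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(
            f"reference matrix is rank deficient; near-collinear cell-type "
            f"pairs: {pairs or 'none by pairwise correlation'}"
        )


def ols_deconvolve(X_star: np.ndarray, Z_hat, cluster_ids=None,
                   method: str = "clipped_ols") -> ProportionMatrix:
    """Cluster-level proportions from pseudo-bulk profiles.

    Parameters
    ----------
    X_star : ndarray (h, g)
        Pseudo-bulk profiles, gene order matching the reference columns.
    Z_hat : ReferenceMatrix or ndarray (k, g)
        Cell-type mean profiles over the marker genes.
    method : {"clipped_ols", "nnls"}
        ``clipped_ols`` (default) solves unconstrained least squares via
        a pseudo-inverse, clips negatives and renormalizes; ``nnls``
        solves the true non-negative problem, then renormalizes.

    A row that is all zero after clipping degenerates to uniform
    proportions with a warning.
    """
    from .marker_selection import ReferenceMatrix

    if isinstance(Z_hat, ReferenceMatrix):
        Z = Z_hat.profiles
        cell_types = Z_hat.cell_type_order
    else:
        Z = np.asarray(Z_hat, dtype=float)
        cell_types = [f"type_{i}" for i in range(Z.shape[0])]
    X_star = np.atleast_2d(np.asarray(X_star, dtype=float))
    if X_star.shape[1] != Z.shape[1]:
        raise ValueError(
            f"gene dimension mismatch: X* has {X_star.shape[1]} genes, "
            f"Ẑ has {Z.shape[1]}"
        )
    k = Z.shape[0]
    if k == 1:
        Y = np.ones((X_star.shape[0], 1))
    else:
        _check_rank(Z, cell_types)
        if method == "nnls":
            Y = np.vstack([_scipy_nnls(Z.T, row)[0] for row in X_star])
        elif method == "clipped_ols":
            # design is Ẑᵀ (g × k); pinv uses SVD, equal to (ẐẐᵀ)⁻¹Ẑ on
            # full-rank input but better conditioned
            Y = (np.linalg.pinv(Z.T) @ X_star.T).T
            Y = np.clip(Y, 0.0, None)
        else:
            raise ValueError(f"unknown method {method!r}")
        sums = Y.sum(axis=1, keepdims=True)
        dead = sums[:, 0] == 0
        if dead.any():
            logger.warning("%d cluster(s) all-zero after clipping; set uniform",
                           int(dead.sum()))
            Y[dead] = 1.0 / k
            sums = Y.sum(axis=1, keepdims=True)
        Y = Y / sums
    if cluster_ids is None:
        cluster_ids = list(range(1, X_star.shape[0] + 1))
    return ProportionMatrix(values=Y, row_ids=list(cluster_ids),
                            cell_type_order=list(cell_types))


def expand_to_spots(cluster_props: ProportionMatrix, final_labels,
                    spot_ids=None) -> ProportionMatrix:
    """Broadcast cluster-level proportions to the member spots."""
    final_labels = np.asarray(final_labels)
    row_of = {c: i for i, c in enumerate(cluster_props.row_ids)}
    missing = sorted(set(final_labels.tolist()) - set(row_of))
    if missing:
        raise ValueError(f"spots labelled with unknown cluster id(s): {missing}")
    idx = np.array([row_of[c] for c in final_labels])
    if spot_ids is None:
        spot_ids = list(range(len(final_labels)))
    return ProportionMatrix(values=cluster_props.values[idx],
                            row_ids=list(spot_ids),
                            cell_type_order=cluster_props.cell_type_order)


@dataclass
class PipelineResult:
    """All intermediates of an end-to-end deconvolution run."""

    clustering: object
    marker_table: object
    reference: object
    cluster_props: ProportionMatrix
    spot_props: ProportionMatrix
    shared_genes: object


def run_pipeline(st, sc, config=None) -> PipelineResult:
    """End-to-end DECLUST: cluster → markers → deconvolve → expand.

    ``config`` is a :class:`~declust.config.RunConfig` (defaults used when
    omitted).  Fully reproducible given ``config.rng_seed``.
    """
    from .config import RunConfig
    from .io_model import intersect_genes, select_variable_genes
    from .marker_selection import build_reference, select_markers
    from .spatial_clustering import cluster_spots, pseudo_bulk

    cfg = config or RunConfig()
    seeds = cfg.stage_seeds()

    st_var = select_variable_genes(st, top_n=cfg.top_n_genes,
                                   use_normalized=cfg.variable_on_normalized)
    sc_var = select_variable_genes(sc, top_n=cfg.top_n_genes,
                                   use_normalized=cfg.variable_on_normalized)
    shared = intersect_genes(st_var, sc_var)

    clustering = cluster_spots(
        st, genes=shared.genes, h=cfg.n_clusters,
        h_min=cfg.h_min, h_max=cfg.h_max, eps=cfg.eps, min_pts=cfg.min_pts,
        frac_threshold=cfg.frac_threshold, seed_frac=cfg.seed_frac,
        rng_seed=seeds["clustering"], neighbor_k=cfg.neighbor_k,
        neighbor_radius=cfg.neighbor_radius,
        min_cluster_size=cfg.min_cluster_size,
    )

    marker_table = select_markers(sc.subset_genes(shared.genes),
                                  t=cfg.t_markers, alpha1=cfg.alpha1,
                                  alpha2=cfg.alpha2)
    reference = build_reference(sc, marker_table)

    st_markers = st.subset_genes(reference.marker_genes)
    X_star, cluster_ids = pseudo_bulk(st_markers.expr, clustering.final_labels,
                                      agg=cfg.pseudobulk_agg)
    cluster_props = ols_deconvolve(X_star, reference, cluster_ids=cluster_ids.tolist(),
                                   method=cfg.deconv_method)
    spot_props = expand_to_spots(cluster_props, clustering.final_labels,
                                 spot_ids=st.spot_ids)
    return PipelineResult(clustering=clustering, marker_table=marker_table,
                          reference=reference, cluster_props=cluster_props,
                          spot_props=spot_props, shared_genes=shared)
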