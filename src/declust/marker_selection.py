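"""Two-statistic marker-gene selection and reference-profile construction.

A gene is a marker for a cell type when it is significantly up-regulated
in that type relative to all other cells (statistic T1, a Welch-type
one-sided t-test with a variance floor) while the remaining types express
it homogeneously (statistic T2, a heterogeneity chi-square over the
per-type means).  Genes pass with ``p(T1) < alpha1`` and
``p(T2) > alpha2``; the top ``t`` passing genes per type, ranked by T1,
form the marker set, and the reference matrix Ẑ (k × g) holds the mean
linear-scale expression of each marker gene within each cell type.

Test statistics are computed on log1p library-size-normalized expression;
Ẑ is built on the linear scale, where the mixing model is linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import SCReference, normalize

logger = logging.getLogger(__name__)

#: variance floor, as a fraction of the across-all-cells gene variance,
#: guarding dropout-heavy genes against zero within-group variance
VAR_FLOOR_FRAC = 0.01


@dataclass
class MarkerTable:
    """Per (gene, cell type) statistics plus the selection outcome."""

    table: pd.DataFrame   # columns: gene, cell_type, t1_stat, t1_p, t2_stat, t2_p, selected, rank

    def markers_for(self, cell_type) -> list:
        sub = self.table[(self.table.cell_type == cell_type) & self.table.selected]
        return sub.sort_values("rank").gene.tolist()

    @property
    def marker_union(self) -> list:
        """Union of all selected markers, sorted for reproducibility."""
        return sorted(set(self.table[self.table.selected].gene))

    @property
    def cell_types(self) -> list:
        return sorted(set(self.table.cell_type))


@dataclass
class ReferenceMatrix:
    """Cell-type × marker-gene mean-expression matrix Ẑ."""

    profiles: np.ndarray      # k × g, linear scale
    cell_type_order: list
    marker_genes: list

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if (self.profiles.sum(axis=1) == 0).any():
            bad = [t for t, row in zip(self.cell_type_order, self.profiles)
                   if row.sum() == 0]
            raise ValueError(f"all-zero reference profile for cell type(s): {bad}")


def _floored_var(x: np.ndarray, floor: float) -> float:
    v = float(np.var(x, ddof=1)) if len(x) > 1 else 0.0
    return max(v, floor)


def t1_statistic(expr_gene: np.ndarray, labels, target_type,
                 var_floor: float | None = None) -> tuple:
    """One-sided Welch t-test of target-type mean minus complement mean.

    Positive statistic ⇒ up-regulated in the target type; the p-value is
    the upper tail.  A variance floor (default: ``VAR_FLOOR_FRAC`` of the
    all-cells variance of the gene) keeps the statistic finite for
    dropout-heavy genes.
    """
    x = np.asarray(expr_gene, dtype=float)
    labels = np.asarray(labels, dtype=object)
    a = x[labels == target_type]
    b = x[labels != target_type]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need ≥ 2 cells in the target type and in the complement")
    if var_floor is None:
        var_floor = VAR_FLOOR_FRAC * float(np.var(x, ddof=1))
    va, vb = _floored_var(a, var_floor), _floored_var(b, var_floor)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf, 0.0) if a.mean() > b.mean() else (-np.inf, 1.0)
    se2 = va / len(a) + vb / len(b)
    stat = float((a.mean() - b.mean()) / np.sqrt(se2))
    # Welch–Satterthwaite degrees of freedom
    df = se2 ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = float(stats.t.sf(stat, df))
    return stat, p


def t2_statistic(expr_gene: np.ndarray, labels, target_type,
                 var_floor: float | None = None) -> tuple:
    """Heterogeneity chi-square across the non-target cell types.

    Cochran's-Q-style statistic ``Q = Σ_c w_c (m_c − m̄_w)²`` with
    ``w_c = 1/SE_c²`` over the remaining types' means; Q is referred to a
    chi-square with (#remaining types − 1) degrees of freedom.  Remaining
    types with < 2 cells are excluded (df reduced, warning).
    """
    x = np.asarray(expr_gene, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if var_floor is None:
        var_floor = VAR_FLOOR_FRAC * float(np.var(x, ddof=1))
    groups = []
    skipped = 0
    for t in sorted(set(labels.tolist())):
        if t == target_type:
            continue
        g = x[labels == t]
        if len(g) < 2:
            skipped += 1
            continue
        groups.append(g)
    if skipped:
        logger.warning("t2_statistic: excluded %d remaining type(s) with < 2 cells",
                       skipped)
    if len(groups) < 2:
        raise ValueError("need ≥ 2 remaining cell types with ≥ 2 cells each")
    means = np.array([g.mean() for g in groups])
    w = np.array([len(g) / _floored_var(g, var_floor) for g in groups])
    grand = float((w * means).sum() / w.sum())
    q = float((w * (means - grand) ** 2).sum())
    df = len(groups) - 1
    p = float(stats.chi2.sf(q, df))
    return q, p


def select_markers(sc_ref: SCReference, genes=None, t: int = 10,
                   alpha1: float = 0.05, alpha2: float = 0.05) -> MarkerTable:
    """Screen every (gene, cell type) pair and keep the top markers.

    Per cell type, genes with ``p(T1) < alpha1`` and ``p(T2) > alpha2``
    are ranked by descending T1 statistic (ties by gene id) and the top
    ``t`` retained.  A cell type with no passing gene falls back to the
    top ``t`` by T1 alone, with a warning.  A gene may serve several cell
    types if it passes for each.
    """
    if genes is None:
        genes = list(sc_ref.gene_ids)
    missing = set(genes) - set(sc_ref.gene_ids)
    if missing:
        raise ValueError(f"genes not in reference: {sorted(missing)[:10]}")
    sub = sc_ref.subset_genes(genes)
    log_expr = normalize(sub.expr, "cpm_log1p")
    labels = np.asarray(sub.cell_types, dtype=object)
    rows = []
    # with only one remaining type, T2 homogeneity holds vacuously
    degenerate_t2 = len(sub.type_order) < 3
    for ct in sub.type_order:
        for j, gene in enumerate(genes):
            col = log_expr[:, j]
            s1, p1 = t1_statistic(col, labels, ct)
            if degenerate_t2:
                s2, p2 = 0.0, 1.0
            else:
                s2, p2 = t2_statistic(col, labels, ct)
            rows.append((gene, ct, s1, p1, s2, p2))
    df = pd.DataFrame(rows, columns=["gene", "cell_type", "t1_stat", "t1_p",
                                     "t2_stat", "t2_p"])
    df["selected"] = False
    df["rank"] = np.nan
    for ct in sub.type_order:
        block = df[df.cell_type == ct]
        passing = block[(block.t1_p < alpha1) & (block.t2_p > alpha2)]
        if passing.empty:
            logger.warning("no gene passes the joint criterion for %r; "
                           "falling back to top %d by T1", ct, t)
            passing = block
        top = passing.sort_values(["t1_stat", "gene"],
                                  ascending=[False, True]).head(t)
        df.loc[top.index, "selected"] = True
        df.loc[top.index, "rank"] = np.arange(1, len(top) + 1)
    return MarkerTable(table=df)


def build_reference(sc_ref: SCReference, marker_table: MarkerTable) -> ReferenceMatrix:
    """Mean linear-scale expression of each marker gene within each type."""
    markers = marker_table.marker_union
    if not markers:
        raise ValueError("marker table selects no genes")
    sub = sc_ref.subset_genes(markers)
    types = sub.type_order
    profiles = np.vstack([
        sub.expr[sub.cells_of_type(ct)].mean(axis=0) for ct in types
    ])
    return ReferenceMatrix(profiles=profiles, cell_type_order=types,
                           marker_genes=markers)
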