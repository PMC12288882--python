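"""Data containers, readers/writers and shared preprocessing.

The two inputs to the pipeline are an ST dataset (spot × gene counts with
2D spot coordinates) and an annotated scRNA-seq reference (cell × gene
counts with one cell-type label per cell).  Expression matrices are kept
as dense ``float64`` arrays; Visium-scale inputs (a few thousand spots,
a few thousand retained genes) fit comfortably.

Coordinate convention: when a Visium tissue-positions table is supplied,
the integer ``array_row``/``array_col`` grid is used as the coordinate
system, so that spatial radii downstream (DBSCAN's ε, the neighbour
radius) are in array-grid units.  Plain 3-column coordinate files are
used as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import issparse

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class STDataset:
    """Spot × gene expression with per-spot 2D coordinates.

    Attributes
    ----------
    spot_ids : list of str
        Spot barcodes, one per row of ``expr``.
    expr : ndarray of shape (n, g_n)
        Non-negative expression (counts or normalized).
    coords : ndarray of shape (n, 2)
        Spot positions in array-grid units.
    gene_ids : list of str
        Gene identifiers, one per column of ``expr``.
    """

    spot_ids: list
    expr: np.ndarray
    coords: np.ndarray
    gene_ids: list

    def __post_init__(self):
        self.expr = np.asarray(self.expr, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.spot_ids)
        if self.expr.shape[0] != n or self.coords.shape[0] != n:
            raise ValueError(
                f"row mismatch: {n} spot ids, expr {self.expr.shape[0]} rows, "
                f"coords {self.coords.shape[0]} rows"
            )
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be n × 2")
        if self.expr.size and self.expr.min() < 0:
            raise ValueError("expression values must be non-negative")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.expr.shape[1] != len(self.gene_ids):
            raise ValueError("gene id count does not match expr columns")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def subset_spots(self, index) -> "STDataset":
        """Row-subset by integer index array or boolean mask."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return STDataset(
            spot_ids=[self.spot_ids[i] for i in idx],
            expr=self.expr[idx],
            coords=self.coords[idx],
            gene_ids=list(self.gene_ids),
        )

    def subset_genes(self, genes) -> "STDataset":
        col = {g: j for j, g in enumerate(self.gene_ids)}
        idx = [col[g] for g in genes]
        return STDataset(self.spot_ids, self.expr[:, idx], self.coords, list(genes))


@dataclass
class SCReference:
    """Cell × gene expression with one cell-type label per cell."""

    cell_ids: list
    expr: np.ndarray
    gene_ids: list
    cell_types: list

    def __post_init__(self):
        self.expr = np.asarray(self.expr, dtype=float)
        m = len(self.cell_ids)
        if self.expr.shape[0] != m or len(self.cell_types) != m:
            raise ValueError("cell ids, expr rows and labels must align")
        if self.expr.size and self.expr.min() < 0:
            raise ValueError("expression values must be non-negative")
        if self.expr.shape[1] != len(self.gene_ids):
            raise ValueError("gene id count does not match expr columns")
        if len(self.type_order) < 2:
            raise ValueError("reference needs at least 2 distinct cell types")

    @property
    def n_cells(self) -> int:
        return self.expr.shape[0]

    @property
    def type_order(self) -> list:
        """Distinct cell-type labels, sorted for reproducibility."""
        return sorted(set(self.cell_types))

    @property
    def k(self) -> int:
        return len(self.type_order)

    def cells_of_type(self, cell_type) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.cell_types, dtype=object) == cell_type)

    def subset_genes(self, genes) -> "SCReference":
        col = {g: j for j, g in enumerate(self.gene_ids)}
        idx = [col[g] for g in genes]
        return SCReference(self.cell_ids, self.expr[:, idx], list(genes), self.cell_types)


@dataclass
class SharedGeneSpace:
    """Ordered gene list shared by an ST dataset and an scRNA-seq reference."""

    genes: list
    st_index: dict = field(repr=False)
    sc_index: dict = field(repr=False)

    @property
    def g(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_VISIUM_COLS = ["barcode", "in_tissue", "array_row", "array_col",
                "pxl_row_in_fullres", "pxl_col_in_fullres"]


def _read_expr_table(path: Path, fmt: str):
    """Return (ids, gene_ids, matrix) from CSV/TSV, matrix-market dir, or HDF5."""
    path = Path(path)
    if fmt == "auto":
        if path.is_dir() or path.suffix == ".mtx":
            fmt = "mtx"
        elif path.suffix in (".h5", ".hdf5"):
            fmt = "h5"
        else:
            fmt = "csv"
    if fmt == "mtx":
        d = path if path.is_dir() else path.parent
        mat = mmread(d / "matrix.mtx")
        if issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        # 10x convention stores genes × barcodes
        return barcodes, genes, np.asarray(mat, dtype=float).T
    if fmt == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["row_ids"][:]]
            genes = [x.decode() if isinstance(x, bytes) else str(x) for x in f["gene_ids"][:]]
            mat = np.asarray(f["expr"][:], dtype=float)
        return ids, genes, mat
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.index.astype(str).tolist(), df.columns.astype(str).tolist(), df.to_numpy(dtype=float)


def _read_coords(path: Path) -> pd.DataFrame:
    """Read a Visium tissue-positions table or a plain id,x,y CSV.

    Returns a frame indexed by barcode with columns x, y, in_tissue.
    """
    path = Path(path)
    head = pd.read_csv(path, nrows=1, header=None)
    has_header = any(isinstance(v, str) and not v.replace(".", "").replace("-", "").isdigit()
                     for v in head.iloc[0, 1:])
    if has_header:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
    else:
        df = pd.read_csv(path, header=None)
        if df.shape[1] == 6:
            df.columns = _VISIUM_COLS
        elif df.shape[1] == 3:
            df.columns = ["barcode", "x", "y"]
        else:
            raise ValueError(
                f"coordinate file {path} has {df.shape[1]} columns; expected 3 or 6"
            )
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if "array_row" in df.columns and "array_col" in df.columns:
        out = pd.DataFrame({"x": df["array_row"], "y": df["array_col"]}, index=df.index)
    else:
        xy = [c for c in df.columns if c not in ("in_tissue",)][:2]
        out = pd.DataFrame({"x": df[xy[0]], "y": df[xy[1]]}, index=df.index)
    out["in_tissue"] = df["in_tissue"].astype(int) if "in_tissue" in df.columns else 1
    return out


def read_st(expr_path, coords_path, format: str = "auto") -> STDataset:
    """Read an ST dataset from an expression file plus a coordinates table.

    Spots flagged ``in_tissue == 0`` are dropped.  Coordinates come from
    ``array_row``/``array_col`` when the table carries them.
    """
    ids, genes, mat = _read_expr_table(Path(expr_path), format)
    if mat.size == 0:
        raise ValueError(f"empty expression matrix in {expr_path}")
    coords = _read_coords(Path(coords_path))
    missing = [b for b in ids if b not in coords.index]
    if missing:
        raise ValueError(
            f"{len(missing)} barcodes missing from coordinates table; "
            f"first 10: {missing[:10]}"
        )
    coords = coords.loc[ids]
    keep = coords["in_tissue"].to_numpy() == 1
    if not keep.any():
        raise ValueError("no in-tissue spots")
    ids = [b for b, k in zip(ids, keep) if k]
    return STDataset(
        spot_ids=ids,
        expr=mat[keep],
        coords=coords.loc[ids, ["x", "y"]].to_numpy(dtype=float),
        gene_ids=genes,
    )


def read_sc(expr_path, labels_path, format: str = "auto") -> SCReference:
    """Read an annotated scRNA-seq reference.

    ``labels_path`` maps cell id → cell-type string (2-column CSV, with or
    without header).  Unlabeled cells are dropped with a logged count.
    """
    ids, genes, mat = _read_expr_table(Path(expr_path), format)
    lab = pd.read_csv(labels_path, header=None, dtype=str)
    if lab.iloc[0, 0].lower() in ("cell_id", "cell", "barcode", "id"):
        lab = lab.iloc[1:]
    label_map = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    keep, labels = [], []
    for i, c in enumerate(ids):
        lbl = label_map.get(c)
        if lbl is None or (isinstance(lbl, float) and np.isnan(lbl)):
            continue
        keep.append(i)
        labels.append(lbl)
    dropped = len(ids) - len(keep)
    if not keep:
        raise ValueError("no labeled cells in reference")
    if dropped:
        logger.warning("dropped %d unlabeled cells", dropped)
    return SCReference(
        cell_ids=[ids[i] for i in keep],
        expr=mat[keep],
        gene_ids=genes,
        cell_types=labels,
    )


def write_st(dataset: STDataset, expr_path, coords_path, format: str = "csv") -> None:
    """Write an ST dataset (CSV or matrix-market triplet directory)."""
    if format == "mtx":
        d = Path(expr_path)
        d.mkdir(parents=True, exist_ok=True)
        from scipy.sparse import csr_matrix

        mmwrite(str(d / "matrix.mtx"), csr_matrix(dataset.expr.T))
        pd.Series(dataset.gene_ids).to_csv(d / "features.tsv", sep="\t",
                                           header=False, index=False)
        pd.Series(dataset.spot_ids).to_csv(d / "barcodes.tsv", sep="\t",
                                           header=False, index=False)
    else:
        pd.DataFrame(dataset.expr, index=dataset.spot_ids,
                     columns=dataset.gene_ids).to_csv(expr_path)
    pd.DataFrame(
        {
            "barcode": dataset.spot_ids,
            "in_tissue": 1,
            "array_row": dataset.coords[:, 0],
            "array_col": dataset.coords[:, 1],
            "pxl_row_in_fullres": dataset.coords[:, 0],
            "pxl_col_in_fullres": dataset.coords[:, 1],
        }
    ).to_csv(coords_path, header=False, index=False)


def write_sc(ref: SCReference, expr_path, labels_path) -> None:
    pd.DataFrame(ref.expr, index=ref.cell_ids, columns=ref.gene_ids).to_csv(expr_path)
    pd.DataFrame({"cell_id": ref.cell_ids, "cell_type": ref.cell_types}).to_csv(
        labels_path, header=False, index=False
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def normalize(expr: np.ndarray, method: str = "cpm_log1p",
              target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalization.

    ``cpm_log1p`` scales each row to ``target_sum`` total then applies
    log1p; ``none`` returns the input unchanged.  All-zero rows are left
    all-zero with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    if method == "none":
        return expr.copy()
    if method != "cpm_log1p":
        raise ValueError(f"unknown normalization method {method!r}")
    sums = expr.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        logger.warning("%d all-zero rows left unnormalized", int(zero.sum()))
    safe = np.where(sums == 0, 1.0, sums)
    return np.log1p(expr / safe * target_sum)


def select_variable_genes(dataset, top_n: int = 5000,
                          use_normalized: bool = True) -> list:
    """Top ``top_n`` most variable genes.

    Variability is the per-gene variance of log1p library-size-normalized
    expression (raw counts when ``use_normalized=False``).  Ties broken by
    gene id so the selection is invariant to input gene order.
    """
    expr = dataset.expr
    if expr.shape[1] == 0:
        raise ValueError("dataset has no genes")
    mat = normalize(expr, "cpm_log1p") if use_normalized else expr
    var = mat.var(axis=0)
    order = sorted(range(len(var)), key=lambda j: (-var[j], dataset.gene_ids[j]))
    return [dataset.gene_ids[j] for j in order[: min(top_n, len(order))]]


def intersect_genes(st_genes, sc_genes) -> SharedGeneSpace:
    """Shared gene space, sorted lexicographically for reproducibility."""
    if not st_genes or not sc_genes:
        raise ValueError("gene lists must be nonempty")
    genes = sorted(set(st_genes) & set(sc_genes))
    if not genes:
        raise ValueError("no overlapping genes between ST data and reference")
    st_pos = {g: j for j, g in enumerate(st_genes)}
    sc_pos = {g: j for j, g in enumerate(sc_genes)}
    return SharedGeneSpace(
        genes=genes,
        st_index={g: st_pos[g] for g in genes},
        sc_index={g: sc_pos[g] for g in genes},
    )
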