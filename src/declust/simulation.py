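"""Simulated ST data and fully synthetic test fixtures.

Two simulators mirror the evaluation designs used for reference-based ST
deconvolution:

* a multinomial mixture simulator: per spot, cell-type counts are drawn
  from ``Multinomial(cells_per_spot, proportions)``, that many cells are
  sampled (with replacement) from the reference pools, and their linear
  counts are summed into the spot profile; the truth matrix S is exactly
  counts / cells_per_spot;
* a ligand–receptor (LR) enriched variant: inside designated clusters,
  the pools for a chosen pair of cell types are restricted to cells whose
  ligand AND receptor expression both reach an upper quantile, mimicking
  co-localized interacting cell types.  Cluster labels, cluster-level
  proportions, and LR gene pairs are inputs.

:func:`make_fixture` builds a matching fully synthetic reference + ST
lattice so the whole pipeline is testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deconvolution import ProportionMatrix
from .io_model import SCReference, STDataset


@dataclass
class LREnrichment:
    """One cluster-level enrichment directive."""

    cluster_id: int
    ligand: str
    receptor: str
    celltype_pair: tuple
    quantile: float = 0.75


@dataclass
class SimulationConfig:
    cells_per_spot: int = 10
    rng_seed: int = 0
    lr_enrichments: list = field(default_factory=list)

    def __post_init__(self):
        if self.cells_per_spot < 1:
            raise ValueError("cells_per_spot must be ≥ 1")


@dataclass
class SimulatedST:
    st: STDataset
    truth: ProportionMatrix
    cell_assignments: list       # per spot, list of sampled reference cell indices


def simulate_spot(proportions, sc_ref: SCReference, cells_per_spot: int,
                  rng: np.random.Generator, pools: dict | None = None):
    """One spot: multinomial cell counts, cells sampled, profiles summed.

    Returns ``(profile, counts, cell_indices)``; ``pools`` optionally
    restricts the per-type candidate cells (used by the LR simulator).
    """
    p = np.asarray(proportions, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    types = sc_ref.type_order
    counts = rng.multinomial(cells_per_spot, p)
    profile = np.zeros(sc_ref.expr.shape[1])
    chosen = []
    for ct, c in zip(types, counts):
        if c == 0:
            continue
        pool = pools[ct] if pools is not None else sc_ref.cells_of_type(ct)
        if len(pool) == 0:
            raise ValueError(f"no reference cells available for type {ct!r}")
        picks = rng.choice(pool, size=c, replace=True)
        profile += sc_ref.expr[picks].sum(axis=0)
        chosen.extend(int(i) for i in picks)
    return profile, counts, chosen


def _broadcast_S(S, n_spots, cluster_labels=None):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.shape[0] == n_spots:
        return S
    if cluster_labels is None:
        raise ValueError("cluster-level S needs cluster_labels to broadcast")
    labels = np.asarray(cluster_labels)
    ids = np.unique(labels)
    if S.shape[0] != len(ids):
        raise ValueError("S rows match neither spots nor clusters")
    row_of = {c: i for i, c in enumerate(ids)}
    return S[[row_of[c] for c in labels]]


def simulate_dataset(st_coords, S, sc_ref: SCReference,
                     config: SimulationConfig | None = None,
                     cluster_labels=None, spot_ids=None,
                     pools_per_spot=None) -> SimulatedST:
    """Multinomial mixture ST dataset on the given coordinates.

    ``S`` holds target proportions per spot (or per cluster, broadcast
    via ``cluster_labels``).  The realized truth is counts/cells_per_spot.
    """
    cfg = config or SimulationConfig()
    coords = np.asarray(st_coords, dtype=float)
    n = coords.shape[0]
    S = _broadcast_S(S, n, cluster_labels)
    rng = np.random.default_rng(cfg.rng_seed)
    if spot_ids is None:
        spot_ids = [f"spot_{i}" for i in range(n)]
    profiles, truth, assignments = [], [], []
    for i in range(n):
        pools = pools_per_spot[i] if pools_per_spot is not None else None
        profile, counts, chosen = simulate_spot(S[i], sc_ref, cfg.cells_per_spot,
                                                rng, pools=pools)
        profiles.append(profile)
        truth.append(counts / cfg.cells_per_spot)
        assignments.append(chosen)
    st = STDataset(spot_ids=list(spot_ids), expr=np.vstack(profiles),
                   coords=coords, gene_ids=list(sc_ref.gene_ids))
    truth_mat = ProportionMatrix(values=np.vstack(truth), row_ids=list(spot_ids),
                                 cell_type_order=sc_ref.type_order)
    return SimulatedST(st=st, truth=truth_mat, cell_assignments=assignments)


def lr_filter_cells(sc_ref: SCReference, ligand: str, receptor: str,
                    quantile: float = 0.75) -> np.ndarray:
    """Cells in the upper quantile for BOTH the ligand and the receptor.

    Quantiles (linear interpolation, ties pass via ≥) are taken over all
    cells.
    """
    gidx = {g: j for j, g in enumerate(sc_ref.gene_ids)}
    for g in (ligand, receptor):
        if g not in gidx:
            raise ValueError(f"gene {g!r} not in reference")
    lig = sc_ref.expr[:, gidx[ligand]]
    rec = sc_ref.expr[:, gidx[receptor]]
    lo_l = np.quantile(lig, quantile)
    lo_r = np.quantile(rec, quantile)
    keep = np.flatnonzero((lig >= lo_l) & (rec >= lo_r))
    if keep.size == 0:
        raise ValueError(
            f"no cell passes the {quantile:.0%} quantile for both "
            f"{ligand!r} and {receptor!r}; lower the quantile"
        )
    return keep


def simulate_lr_enriched(st_coords, cluster_labels, S_cluster,
                         sc_ref: SCReference, lr_enrichments,
                         config: SimulationConfig | None = None,
                         spot_ids=None) -> SimulatedST:
    """Mixture simulation with LR-restricted pools in enriched clusters.

    In a cluster named by an enrichment, the sampling pools for the two
    named cell types are intersected with the LR-passing cell set;
    everywhere else pools are unrestricted.
    """
    cfg = config or SimulationConfig()
    labels = np.asarray(cluster_labels)
    n = np.asarray(st_coords).shape[0]
    if labels.shape[0] != n:
        raise ValueError("cluster_labels must cover all spots")
    base_pools = {ct: sc_ref.cells_of_type(ct) for ct in sc_ref.type_order}
    per_cluster = {}
    for enr in lr_enrichments:
        enr = enr if isinstance(enr, LREnrichment) else LREnrichment(*enr)
        if enr.cluster_id not in set(labels.tolist()):
            raise ValueError(f"enrichment names unknown cluster {enr.cluster_id}")
        passing = set(lr_filter_cells(sc_ref, enr.ligand, enr.receptor,
                                      enr.quantile).tolist())
        pools = dict(base_pools)
        for ct in enr.celltype_pair:
            if ct not in pools:
                raise ValueError(f"enrichment names unknown cell type {ct!r}")
            restricted = np.array(sorted(set(pools[ct].tolist()) & passing), dtype=int)
            if restricted.size == 0:
                raise ValueError(
                    f"no {ct!r} cell passes the LR filter for "
                    f"({enr.ligand}, {enr.receptor})"
                )
            pools[ct] = restricted
        per_cluster[enr.cluster_id] = pools
    pools_per_spot = [per_cluster.get(int(c), base_pools) for c in labels]
    return simulate_dataset(st_coords, S_cluster, sc_ref, cfg,
                            cluster_labels=labels, spot_ids=spot_ids,
                            pools_per_spot=pools_per_spot)


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def _quadrant_layout(side: int) -> np.ndarray:
    """Domain id (1..4) per spot on a side × side lattice, by quadrant."""
    coords = np.array([(r, c) for r in range(side) for c in range(side)])
    half = side / 2
    return (coords[:, 0] >= half).astype(int) * 2 + (coords[:, 1] >= half).astype(int) + 1


def _stripe_layout(side: int, k: int) -> np.ndarray:
    coords = np.array([(r, c) for r in range(side) for c in range(side)])
    return (coords[:, 0] * k // side) + 1


def make_fixture(n_spots: int = 400, n_genes: int = 200, k: int = 4,
                 n_cells_per_type: int = 50, markers_per_type: int = 10,
                 effect_size: float = 4.0, domain_layout: str = "quadrants",
                 rng_seed: int = 0, cells_per_spot: int = 10,
                 dominant_frac: float = 0.8, nb_dispersion: float = 0.5):
    """Fully synthetic reference + ST lattice with known ground truth.

    The reference has ``k`` cell types of ``n_cells_per_type`` cells with
    negative-binomial baseline counts (log-normal per-gene means,
    dispersion ``nb_dispersion``) and ``markers_per_type`` planted marker
    genes per type whose mean is multiplied by ``effect_size`` in that
    type only.  Spots sit on a square lattice partitioned into contiguous
    domains ("quadrants" for k=4, horizontal "stripes" otherwise); each
    domain's proportion vector gives ``dominant_frac`` to its own type
    and splits the rest evenly.  The ST matrix comes from
    :func:`simulate_dataset`.

    Returns ``(sc_ref, simulated, domain_labels)`` where ``simulated``
    carries the realized truth S.
    """
    rng = np.random.default_rng(rng_seed)
    side = int(round(np.sqrt(n_spots)))
    n_spots = side * side
    gene_ids = [f"g{j:04d}" for j in range(n_genes)]
    types = [f"type_{i}" for i in range(k)]
    if k * markers_per_type > n_genes:
        raise ValueError("need n_genes ≥ k × markers_per_type")

    base_mean = rng.lognormal(mean=1.0, sigma=0.6, size=n_genes)
    marker_of = {}                       # gene column -> owning type index
    for i in range(k):
        for j in range(i * markers_per_type, (i + 1) * markers_per_type):
            marker_of[j] = i

    cells, labels = [], []
    for i, ct in enumerate(types):
        mu = base_mean.copy()
        for j, owner in marker_of.items():
            if owner == i:
                mu[j] *= effect_size
        # NB via gamma-Poisson; r = 1/dispersion
        r = 1.0 / nb_dispersion
        lam = rng.gamma(shape=r, scale=mu / r, size=(n_cells_per_type, n_genes))
        cells.append(rng.poisson(lam))
        labels.extend([ct] * n_cells_per_type)
    sc_ref = SCReference(
        cell_ids=[f"cell_{i}" for i in range(k * n_cells_per_type)],
        expr=np.vstack(cells).astype(float), gene_ids=gene_ids, cell_types=labels,
    )

    if domain_layout == "quadrants":
        if k != 4:
            raise ValueError('domain_layout "quadrants" requires k=4')
        domains = _quadrant_layout(side)
    elif domain_layout == "stripes":
        domains = _stripe_layout(side, k)
    else:
        raise ValueError(f"unknown domain_layout {domain_layout!r}")
    coords = np.array([(r, c) for r in range(side) for c in range(side)], dtype=float)

    off = (1.0 - dominant_frac) / (k - 1)
    S_domain = np.full((k, k), off)
    np.fill_diagonal(S_domain, dominant_frac)

    sim = simulate_dataset(
        coords, S_domain, sc_ref,
        SimulationConfig(cells_per_spot=cells_per_spot,
                         rng_seed=int(rng.integers(2 ** 31))),
        cluster_labels=domains,
    )
    return sc_ref, sim, domains
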