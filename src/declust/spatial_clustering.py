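"""Spatial clustering of spots: hierarchical → DBSCAN → seeds → region growing.

The pipeline first clusters spots on expression alone (Ward-linkage
agglomerative clustering, cluster count chosen at the elbow of the WCSS
curve).  Expression-only clusters ignore spatial continuity, so DBSCAN is
run on the coordinates of each cluster's spots to carve out dense spatial
sub-clusters; isolated spots become NOISE.  Half of the interior spots of
every sufficiently large sub-cluster are sampled as seeds, and a seeded
region growing (SRG) pass then assigns every spot — seeds keep their
labels, all other spots (including NOISE) are absorbed into the adjacent
region with the most similar running mean expression.

Spatial neighbours throughout are the ``k`` nearest spots by Euclidean
coordinate distance within a radius cap (defaults ``k=8``, radius 2 grid
units), which covers both square lattices and the hex-packed Visium
array.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass
class HierarchicalResult:
    """Expression-only clustering plus the WCSS curve used to pick h."""

    labels: np.ndarray            # per-spot initial cluster id, 1..h0
    wcss_curve: dict              # candidate h -> WCSS
    chosen_h: int


@dataclass
class SeedSet:
    """Seeds for region growing, labelled by their spatial sub-cluster."""

    seed_spots: np.ndarray        # indices into the spot array
    seed_labels: np.ndarray       # region label per seed
    subcluster_of: np.ndarray     # per-spot region label, or NOISE


@dataclass
class ClusteringResult:
    final_labels: np.ndarray      # per-spot cluster id in 1..h
    n_clusters: int
    seed_set: SeedSet = field(repr=False, default=None)
    hierarchical: HierarchicalResult = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# hierarchical stage
# ---------------------------------------------------------------------------

def wcss(expr: np.ndarray, labels) -> float:
    """Within-cluster sum of squares.

    Sum over clusters of the squared Euclidean distance of each member's
    expression profile to the cluster mean profile.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != expr.shape[0]:
        raise ValueError("labels must cover every row of expr")
    total = 0.0
    for lab in np.unique(labels):
        block = expr[labels == lab]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def _ward_tree(expr: np.ndarray):
    return linkage(np.asarray(expr, dtype=float), method="ward")


def hierarchical_cluster(expr: np.ndarray, h: int, tree=None) -> np.ndarray:
    """Ward-linkage agglomerative clustering into ``h`` clusters (labels 1..h)."""
    expr = np.asarray(expr, dtype=float)
    n = expr.shape[0]
    if not 1 <= h <= n:
        raise ValueError(f"h={h} outside [1, {n}]")
    if h == n:
        return np.arange(1, n + 1)
    if tree is None:
        tree = _ward_tree(expr)
    return fcluster(tree, t=h, criterion="maxclust")


def choose_h_elbow(expr: np.ndarray, h_min: int = 2, h_max: int = 15) -> HierarchicalResult:
    """Pick the cluster count at the elbow of the WCSS curve.

    The curve is computed for every h in [h_min, h_max] from one Ward
    tree (nested partitions, so the curve is non-increasing).  The elbow
    is automated as the h maximizing the discrete second difference
    ``wcss[h-1] - 2 wcss[h] + wcss[h+1]``; a flat curve falls back to
    ``h_min`` with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    n = expr.shape[0]
    h_max = min(h_max, n)
    if not 1 <= h_min < h_max:
        raise ValueError(f"need 1 <= h_min < h_max <= n; got {h_min}, {h_max}")
    tree = _ward_tree(expr)
    hs = list(range(h_min, h_max + 1))
    labelings = {h: hierarchical_cluster(expr, h, tree=tree) for h in hs}
    curve = {h: wcss(expr, labelings[h]) for h in hs}
    vals = np.array([curve[h] for h in hs])
    if np.allclose(vals, vals[0]):
        logger.warning("flat WCSS curve; falling back to h_min=%d", h_min)
        chosen = h_min
    elif len(hs) < 3:
        chosen = hs[int(np.argmin(vals))]
    else:
        second = vals[:-2] - 2 * vals[1:-1] + vals[2:]
        chosen = hs[1 + int(np.argmax(second))]
    return HierarchicalResult(labels=labelings[chosen], wcss_curve=curve, chosen_h=chosen)


# ---------------------------------------------------------------------------
# DBSCAN sub-clustering and seed selection
# ---------------------------------------------------------------------------

def dbscan_subclusters(coords: np.ndarray, member_mask, eps: float = 4.0,
                       min_pts: int = 8) -> np.ndarray:
    """DBSCAN on the coordinates of one initial cluster's spots.

    Returns a full-length array: non-members hold NOISE position values of
    -2, members get a sub-cluster id ≥ 0 or NOISE (-1).
    """
    coords = np.asarray(coords, dtype=float)
    member_mask = np.asarray(member_mask, dtype=bool)
    out = np.full(coords.shape[0], -2, dtype=int)
    pts = coords[member_mask]
    if pts.shape[0] == 0:
        return out
    if pts.shape[0] < min_pts:
        out[member_mask] = NOISE
        return out
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    out[member_mask] = labels
    return out


def spatial_neighbors(coords: np.ndarray, k: int = 8, radius: float = 2.0) -> list:
    """Per-spot neighbour lists: the k nearest spots within ``radius``.

    Euclidean distance on array-grid coordinates; radius 2 covers the
    8-neighbourhood of a square lattice and the 6+2 ring of the Visium
    hex layout.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=min(k + 1, n))
    nbrs = []
    for i in range(n):
        row = [int(j) for d, j in zip(np.atleast_1d(dist[i]), np.atleast_1d(idx[i]))
               if j != i and d <= radius + 1e-9]
        nbrs.append(row[:k])
    return nbrs


def boundary_mask(coords: np.ndarray, k: int = 8, radius: float = 2.0) -> np.ndarray:
    """Tissue-boundary spots: fewer than the full complement of neighbours."""
    nbrs = spatial_neighbors(coords, k=k, radius=radius)
    return np.array([len(nb) < k for nb in nbrs])


def select_seeds(subclusters: list, coords: np.ndarray, total_n: int,
                 frac_threshold: float = 0.05, seed_frac: float = 0.5,
                 rng_seed: int = 0, neighbor_k: int = 8,
                 neighbor_radius: float = 2.0) -> SeedSet:
    """Sample SRG seeds from the spatial sub-clusters.

    ``subclusters`` is a list of per-initial-cluster arrays as returned by
    :func:`dbscan_subclusters`.  Sub-clusters holding less than
    ``frac_threshold`` of all spots contribute no seeds; from the rest,
    ``floor(seed_frac × eligible)`` non-boundary spots are drawn uniformly
    without replacement.  Region labels are assigned consecutively over
    (initial cluster, sub-cluster) pairs.
    """
    rng = np.random.default_rng(rng_seed)
    n = np.asarray(coords).shape[0]
    on_boundary = boundary_mask(coords, k=neighbor_k, radius=neighbor_radius)
    region_of = np.full(n, NOISE, dtype=int)
    seed_spots, seed_labels = [], []
    next_label = 1
    for sub in subclusters:
        sub = np.asarray(sub)
        for sc_id in sorted(set(sub[sub >= 0].tolist())):
            members = np.flatnonzero(sub == sc_id)
            region = next_label
            next_label += 1
            region_of[members] = region
            if len(members) < frac_threshold * total_n:
                continue
            eligible = members[~on_boundary[members]]
            if len(eligible) == 0:
                logger.warning("sub-cluster %d has only boundary spots; 0 seeds", region)
                continue
            n_seeds = int(np.floor(seed_frac * len(eligible)))
            if n_seeds == 0:
                continue
            chosen = rng.choice(eligible, size=n_seeds, replace=False)
            chosen.sort()
            seed_spots.extend(chosen.tolist())
            seed_labels.extend([region] * n_seeds)
    if not seed_spots:
        raise ValueError("no seeds selected; relax frac_threshold or seed_frac")
    return SeedSet(
        seed_spots=np.array(seed_spots, dtype=int),
        seed_labels=np.array(seed_labels, dtype=int),
        subcluster_of=region_of,
    )


# ---------------------------------------------------------------------------
# seeded region growing
# ---------------------------------------------------------------------------

class _Region:
    """Running mean expression of a growing region."""

    __slots__ = ("total", "count")

    def __init__(self, g):
        self.total = np.zeros(g)
        self.count = 0

    def add(self, profile):
        self.total += profile
        self.count += 1

    @property
    def mean(self):
        return self.total / self.count


def srg(expr: np.ndarray, coords: np.ndarray, seed_set: SeedSet,
        neighbor_k: int = 8, neighbor_radius: float = 2.0,
        min_cluster_size: int = 3) -> ClusteringResult:
    """Seeded region growing over the spot lattice.

    A sequentially sorted list (a heap) holds the unlabeled spatial
    neighbours of the labelled region, keyed by the Euclidean distance
    between the spot's expression profile and the running mean profile of
    the adjacent region (ties broken by spot index).  Each iteration pops
    the closest spot and labels it: the unanimous label of its labelled
    neighbours if they agree, otherwise the label of the
    expression-nearest adjacent region.  Region means update as spots
    join.  Disconnected spots never reached by growth are assigned to the
    expression-nearest region afterwards; clusters that end up smaller
    than ``min_cluster_size`` are merged into the expression-nearest
    other cluster.  Final labels are 1..h by decreasing cluster size.
    """
    expr = np.asarray(expr, dtype=float)
    n, g = expr.shape
    if len(seed_set.seed_spots) == 0:
        raise ValueError("seed set is empty")
    nbrs = spatial_neighbors(coords, k=neighbor_k, radius=neighbor_radius)

    labels = np.zeros(n, dtype=int)          # 0 = unlabeled
    regions: dict[int, _Region] = {}
    for spot, lab in zip(seed_set.seed_spots, seed_set.seed_labels):
        labels[spot] = lab
        regions.setdefault(lab, _Region(g)).add(expr[spot])

    heap: list = []

    def push_neighbors(p):
        for q in nbrs[p]:
            if labels[q] == 0:
                d = float(np.linalg.norm(expr[q] - regions[labels[p]].mean))
                heapq.heappush(heap, (d, q))

    for spot in seed_set.seed_spots:
        push_neighbors(spot)

    while heap:
        _, p = heapq.heappop(heap)
        if labels[p] != 0:
            continue
        nb_labels = sorted({int(labels[q]) for q in nbrs[p] if labels[q] != 0})
        if not nb_labels:       # stale entry; spot re-enters via a later push
            continue
        if len(nb_labels) == 1:
            lab = nb_labels[0]
        else:
            lab = min(nb_labels,
                      key=lambda l: (float(np.linalg.norm(expr[p] - regions[l].mean)), l))
        labels[p] = lab
        regions[lab].add(expr[p])
        push_neighbors(p)

    unreached = np.flatnonzero(labels == 0)
    if unreached.size:
        logger.warning("%d disconnected spots assigned to nearest region by expression",
                       unreached.size)
        for p in unreached:
            lab = min(regions,
                      key=lambda l: (float(np.linalg.norm(expr[p] - regions[l].mean)), l))
            labels[p] = lab
            regions[lab].add(expr[p])

    # merge undersized clusters into the expression-nearest other cluster
    seed_mask = np.zeros(n, dtype=bool)
    seed_mask[seed_set.seed_spots] = True
    while True:
        labs, counts = np.unique(labels, return_counts=True)
        small = [l for l, c in zip(labs, counts) if c < min_cluster_size]
        if not small or len(labs) == 1:
            break
        l = small[0]
        others = [o for o in labs if o != l]
        mean_l = expr[labels == l].mean(axis=0)
        tgt = min(others,
                  key=lambda o: (float(np.linalg.norm(mean_l - expr[labels == o].mean(axis=0))), o))
        logger.info("merging cluster %d (%d spots) into %d",
                    l, int(counts[labs.tolist().index(l)]), tgt)
        labels[labels == l] = tgt

    # relabel 1..h by decreasing size (ties by old label for determinism)
    labs, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(labs)), key=lambda i: (-counts[i], labs[i]))
    remap = {int(labs[i]): rank + 1 for rank, i in enumerate(order)}
    final = np.array([remap[int(l)] for l in labels], dtype=int)
    return ClusteringResult(final_labels=final, n_clusters=len(labs),
                            seed_set=seed_set, hierarchical=None)


# ---------------------------------------------------------------------------
# aggregation and orchestration
# ---------------------------------------------------------------------------

def pseudo_bulk(expr_linear: np.ndarray, final_labels, agg: str = "mean"):
    """Aggregate linear-scale spot expression into per-cluster profiles.

    Returns ``(X_star, cluster_ids)`` with one row per cluster id in
    ascending order.  Mean aggregation (default) keeps cluster size from
    scaling the response; ``agg="sum"`` is available.
    """
    expr_linear = np.asarray(expr_linear, dtype=float)
    final_labels = np.asarray(final_labels)
    cluster_ids = np.unique(final_labels)
    rows = []
    for c in cluster_ids:
        block = expr_linear[final_labels == c]
        rows.append(block.sum(axis=0) if agg == "sum" else block.mean(axis=0))
    return np.vstack(rows), cluster_ids


def cluster_spots(st, genes=None, h=None, h_min: int = 2, h_max: int = 15,
                  eps: float = 4.0, min_pts: int = 8,
                  frac_threshold: float = 0.05, seed_frac: float = 0.5,
                  rng_seed: int = 0, neighbor_k: int = 8,
                  neighbor_radius: float = 2.0,
                  min_cluster_size: int = 3) -> ClusteringResult:
    """Full clustering stage on an :class:`~declust.io_model.STDataset`.

    ``genes`` restricts the expression space (typically the shared
    variable-gene set); clustering distances use log1p library-size
    normalized expression.
    """
    from .io_model import normalize

    ds = st if genes is None else st.subset_genes(genes)
    norm = normalize(ds.expr, "cpm_log1p")
    if h is None:
        hier = choose_h_elbow(norm, h_min=h_min, h_max=min(h_max, ds.n_spots - 1))
    else:
        hier = HierarchicalResult(labels=hierarchical_cluster(norm, h),
                                  wcss_curve={}, chosen_h=h)
    subs = [dbscan_subclusters(st.coords, hier.labels == c, eps=eps, min_pts=min_pts)
            for c in np.unique(hier.labels)]
    seeds = select_seeds(subs, st.coords, total_n=ds.n_spots,
                         frac_threshold=frac_threshold, seed_frac=seed_frac,
                         rng_seed=rng_seed, neighbor_k=neighbor_k,
                         neighbor_radius=neighbor_radius)
    result = srg(norm, st.coords, seeds, neighbor_k=neighbor_k,
                 neighbor_radius=neighbor_radius, min_cluster_size=min_cluster_size)
    result.hierarchical = hier
    return result
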