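import numpy as np
import pytest

from declust.io_model import normalize
from declust.spatial_clustering import (
    NOISE,
    SeedSet,
    boundary_mask,
    choose_h_elbow,
    cluster_spots,
    dbscan_subclusters,
    hierarchical_cluster,
    pseudo_bulk,
    select_seeds,
    spatial_neighbors,
    srg,
    wcss,
)


from _oracles import brute_dbscan, brute_wcss


def lattice(side):
    return np.array([(r, c) for r in range(side) for c in range(side)], dtype=float)


# ---------------------------------------------------------------------------
# WCSS
# ---------------------------------------------------------------------------

class TestWCSS:
    def test_identical_spots_zero(self):
        expr = np.ones((6, 3))
        assert wcss(expr, [1, 1, 2, 2, 3, 3]) == 0.0

    def test_two_point_closed_form(self):
        assert wcss(np.array([[0.0], [2.0]]), [1, 1]) == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        expr = rng.normal(size=(20, 5))
        labels = rng.integers(1, 4, size=20)
        assert wcss(expr, labels) == pytest.approx(brute_wcss(expr, labels))

    def test_permutation_invariant(self, rng):
        expr = rng.normal(size=(15, 4))
        labels = rng.integers(1, 3, size=15)
        perm = rng.permutation(15)
        gperm = rng.permutation(4)
        assert wcss(expr[perm][:, gperm], labels[perm]) == \
            pytest.approx(wcss(expr, labels))


# ---------------------------------------------------------------------------
# hierarchical stage
# ---------------------------------------------------------------------------

class TestHierarchical:
    def test_two_blobs_separated_exactly(self, rng):
        a = rng.normal(0, 0.1, size=(10, 3))
        b = rng.normal(10, 0.1, size=(12, 3))
        expr = np.vstack([a, b])
        labels = hierarchical_cluster(expr, 2)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_h_equals_1_and_n(self, rng):
        expr = rng.normal(size=(5, 2))
        assert len(set(hierarchical_cluster(expr, 1))) == 1
        assert len(set(hierarchical_cluster(expr, 5))) == 5

    def test_h_above_n_raises(self, rng):
        with pytest.raises(ValueError):
            hierarchical_cluster(rng.normal(size=(4, 2)), 5)

    def test_elbow_recovers_three_blobs(self, rng):
        # three equidistant centers so every 2-cluster merge is equally bad
        centers = np.array([[0, 0, 0, 0], [8, 0, 0, 0], [0, 8, 0, 0]])
        blobs = [rng.normal(c, 0.2, size=(15, 4)) for c in centers]
        res = choose_h_elbow(np.vstack(blobs), h_min=1, h_max=8)
        assert res.chosen_h == 3

    def test_elbow_flat_curve_falls_back(self):
        res = choose_h_elbow(np.ones((10, 3)), h_min=2, h_max=5)
        assert res.chosen_h == 2

    def test_wcss_curve_non_increasing(self, rng):
        expr = rng.normal(size=(30, 4))
        res = choose_h_elbow(expr, h_min=1, h_max=10)
        vals = [res.wcss_curve[h] for h in sorted(res.wcss_curve)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# DBSCAN sub-clustering
# ---------------------------------------------------------------------------

class TestDBSCAN:
    def test_dense_patch_one_subcluster(self):
        pts = np.array([(r, c) for r in range(3) for c in range(3)
                        if (r, c) != (1, 1)], dtype=float)
        out = dbscan_subclusters(pts, np.ones(8, dtype=bool), eps=4, min_pts=8)
        assert set(out.tolist()) == {0}

    def test_far_spot_is_noise(self):
        pts = np.vstack([lattice(4), [[100.0, 100.0]]])
        out = dbscan_subclusters(pts, np.ones(17, dtype=bool), eps=4, min_pts=8)
        assert out[-1] == NOISE
        assert set(out[:-1].tolist()) == {0}

    def test_two_patches_two_subclusters(self):
        pts = np.vstack([lattice(4), lattice(4) + 50.0])
        out = dbscan_subclusters(pts, np.ones(32, dtype=bool), eps=4, min_pts=8)
        assert len(set(out.tolist()) - {NOISE}) == 2

    def test_below_min_pts_all_noise(self):
        out = dbscan_subclusters(lattice(2), np.ones(4, dtype=bool),
                                 eps=4, min_pts=8)
        assert set(out.tolist()) == {NOISE}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.vstack([
            rng.uniform(0, 10, size=(60, 2)),
            rng.uniform(40, 45, size=(40, 2)),
        ])
        ours = dbscan_subclusters(pts, np.ones(len(pts), dtype=bool),
                                  eps=3, min_pts=6)
        ref = brute_dbscan(pts, eps=3, min_pts=6)
        # same noise set and same partition (labels up to renaming)
        assert set(np.flatnonzero(ours == NOISE)) == set(np.flatnonzero(ref == NOISE))
        mapping = {}
        for a, b in zip(ours, ref):
            if a == NOISE:
                continue
            assert mapping.setdefault(a, b) == b


# ---------------------------------------------------------------------------
# seed selection
# ---------------------------------------------------------------------------

class TestSeedSelection:
    def _one_subcluster(self, coords, members):
        sub = np.full(len(coords), -2)
        sub[members] = 0
        return [sub]

    def test_small_subcluster_contributes_no_seeds(self):
        coords = lattice(10)
        subs = self._one_subcluster(coords, list(range(4)))
        with pytest.raises(ValueError, match="no seeds"):
            select_seeds(subs, coords, total_n=100)

    def test_half_of_interior_spots_sampled(self):
        coords = lattice(10)
        interior = [i for i in range(100)
                    if not boundary_mask(coords)[i]][:10]
        subs = self._one_subcluster(coords, interior)
        seeds = select_seeds(subs, coords, total_n=100, rng_seed=0)
        assert len(seeds.seed_spots) == 5          # floor(0.5 × 10)
        assert set(seeds.seed_spots.tolist()) <= set(interior)

    def test_boundary_spots_excluded(self):
        coords = lattice(10)
        border = [i for i in range(100) if boundary_mask(coords)[i]]
        subs = self._one_subcluster(coords, border[:20])
        with pytest.raises(ValueError, match="no seeds"):
            select_seeds(subs, coords, total_n=100)

    def test_deterministic_given_seed(self):
        coords = lattice(10)
        members = list(range(20, 60))
        subs = self._one_subcluster(coords, members)
        a = select_seeds(subs, coords, 100, rng_seed=7)
        b = select_seeds(subs, coords, 100, rng_seed=7)
        np.testing.assert_array_equal(a.seed_spots, b.seed_spots)


# ---------------------------------------------------------------------------
# seeded region growing
# ---------------------------------------------------------------------------

class TestSRG:
    def test_single_seed_labels_everything(self):
        coords = lattice(5)
        expr = np.ones((25, 3))
        seeds = SeedSet(seed_spots=np.array([12]), seed_labels=np.array([1]),
                        subcluster_of=np.full(25, NOISE))
        res = srg(expr, coords, seeds, min_cluster_size=1)
        assert set(res.final_labels.tolist()) == {1}

    def test_two_blob_partition_recovered(self):
        coords = lattice(6)
        left = coords[:, 1] < 3
        expr = np.where(left[:, None], 0.0, 10.0) + np.zeros((36, 4))
        seeds = SeedSet(
            seed_spots=np.array([0, 35]),
            seed_labels=np.array([1, 2]),
            subcluster_of=np.full(36, NOISE),
        )
        res = srg(expr, coords, seeds, min_cluster_size=1)
        got_left = set(res.final_labels[left].tolist())
        got_right = set(res.final_labels[~left].tolist())
        assert len(got_left) == 1 and len(got_right) == 1
        assert got_left != got_right

    def test_every_spot_labeled_and_seeds_fixed(self, small_fixture):
        sc_ref, sim, domains = small_fixture
        norm = normalize(sim.st.expr, "cpm_log1p")
        sub = np.where(domains == 1, 0, -1)
        seeds = select_seeds([sub], sim.st.coords, 100, rng_seed=3)
        res = srg(norm, sim.st.coords, seeds)
        assert (res.final_labels > 0).all()
        # seeds keep their (possibly renumbered) region: all seeds of one
        # region must share one final label
        seed_finals = res.final_labels[seeds.seed_spots]
        assert len(set(seed_finals.tolist())) == 1

    def test_seed_labels_are_fixed_points_two_regions(self):
        coords = lattice(6)
        rng = np.random.default_rng(5)
        expr = rng.normal(size=(36, 3)) ** 2
        seeds = SeedSet(seed_spots=np.array([0, 1, 34, 35]),
                        seed_labels=np.array([1, 1, 2, 2]),
                        subcluster_of=np.full(36, NOISE))
        res = srg(expr, coords, seeds, min_cluster_size=1)
        f = res.final_labels
        assert f[0] == f[1] and f[34] == f[35] and f[0] != f[35]

    def test_disconnected_spot_assigned_by_expression(self):
        coords = np.vstack([lattice(4), [[50.0, 50.0]]])
        expr = np.zeros((17, 2))
        expr[16] = 0.1
        seeds = SeedSet(seed_spots=np.array([0]), seed_labels=np.array([1]),
                        subcluster_of=np.full(17, NOISE))
        res = srg(expr, coords, seeds, min_cluster_size=1)
        assert res.final_labels[16] == res.final_labels[0]


# ---------------------------------------------------------------------------
# pseudo-bulk and the full stage
# ---------------------------------------------------------------------------

class TestPseudoBulk:
    def test_identical_spots_mean_is_profile(self):
        expr = np.tile([2.0, 4.0], (5, 1))
        X, ids = pseudo_bulk(expr, np.ones(5, dtype=int))
        np.testing.assert_allclose(X, [[2.0, 4.0]])

    def test_mean_closed_form(self):
        X, _ = pseudo_bulk(np.array([[2.0, 0.0], [0.0, 2.0]]), [1, 1])
        np.testing.assert_allclose(X, [[1.0, 1.0]])

    def test_matches_group_by_brute_force(self, rng):
        expr = rng.normal(size=(30, 6)) ** 2
        labels = rng.integers(1, 5, size=30)
        X, ids = pseudo_bulk(expr, labels)
        for row, c in zip(X, ids):
            np.testing.assert_allclose(row, expr[labels == c].mean(axis=0))


class TestFullClusteringStage:
    def test_planted_domains_recovered(self, small_fixture):
        from sklearn.metrics import adjusted_rand_score

        sc_ref, sim, domains = small_fixture
        res = cluster_spots(sim.st, rng_seed=1)
        assert adjusted_rand_score(domains, res.final_labels) >= 0.9

    def test_bit_reproducible(self, small_fixture):
        sc_ref, sim, _ = small_fixture
        a = cluster_spots(sim.st, rng_seed=5)
        b = cluster_spots(sim.st, rng_seed=5)
        np.testing.assert_array_equal(a.final_labels, b.final_labels)


class TestNeighbors:
    def test_interior_lattice_spot_has_8_neighbors(self):
        nbrs = spatial_neighbors(lattice(5), k=8, radius=2.0)
        assert len(nbrs[12]) == 8       # center of the 5×5 grid

    def test_corner_is_boundary(self):
        mask = boundary_mask(lattice(5))
        assert mask[0] and mask[4] and mask[20] and mask[24]
        assert not mask[12]
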