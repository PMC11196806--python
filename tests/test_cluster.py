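import numpy as np
import pytest

from eegperm.cluster import (
    AdjacencyGraph,
    build_adjacency,
    cluster_permutation_test,
    exact_enumeration_test,
    find_clusters,
    paired_tstat,
)
from eegperm.montage import Montage


def _chain_adjacency(n=4):
    """A-B-C-D chain graph."""
    mat = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        mat[i, i + 1] = mat[i + 1, i] = True
    return AdjacencyGraph(labels=tuple("ABCD"[:n]), matrix=mat)


class TestAdjacency:
    def test_zero_threshold_gives_no_neighbors(self, montage62):
        with pytest.warns(UserWarning, match="isolated"):
            g = build_adjacency(montage62, distance_threshold=0.0)
        assert g.matrix.sum() == 0

    def test_huge_threshold_gives_complete_graph(self, montage62):
        g = build_adjacency(montage62, distance_threshold=10.0)
        n = g.n_channels
        assert g.matrix.sum() == n * (n - 1)

    def test_default_threshold_yields_single_component(self, adjacency62):
        assert adjacency62.is_connected()
        assert adjacency62.matrix.sum(axis=1).min() >= 1

    def test_symmetry_and_no_self_loops_enforced(self):
        bad = np.array([[True, True], [True, False]])
        with pytest.raises(ValueError, match="self-neighbors"):
            AdjacencyGraph(labels=("a", "b"), matrix=bad)
        asym = np.array([[False, True], [False, False]])
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencyGraph(labels=("a", "b"), matrix=asym)


class TestPairedT:
    def test_hand_computed_value(self):
        pre = np.zeros((3, 1))
        post = np.array([[1.0], [2.0], [3.0]])
        assert paired_tstat(pre, post)[0] == pytest.approx(3.4641, abs=1e-4)

    def test_identical_conditions_give_zero_with_warning(self):
        x = np.arange(12, dtype=float).reshape(4, 3)
        with pytest.warns(UserWarning, match="zero-variance"):
            t = paired_tstat(x, x)
        assert (t == 0).all()

    def test_antisymmetry(self, rng):
        pre = rng.normal(size=(6, 5))
        post = rng.normal(size=(6, 5))
        np.testing.assert_allclose(
            paired_tstat(pre, post), -paired_tstat(post, pre)
        )

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            paired_tstat(np.zeros((2, 4)), np.ones((2, 4)))


class TestFindClusters:
    def test_chain_splits_at_subthreshold_gap(self):
        clusters = find_clusters(np.array([3.0, 3.0, 0.0, 3.0]), 2.0, _chain_adjacency())
        masses = sorted(c.mass for c in clusters)
        assert masses == [3.0, 6.0]
        assert {c.channels for c in clusters} == {("A", "B"), ("D",)}

    def test_all_subthreshold_gives_no_clusters(self):
        assert find_clusters(np.array([1.0, -1.5, 0.5, 1.9]), 2.0, _chain_adjacency()) == []

    def test_opposite_signs_never_merge(self):
        clusters = find_clusters(np.array([3.0, -3.0]), 2.0, _chain_adjacency(2))
        assert {(c.sign, c.mass) for c in clusters} == {(1, 3.0), (-1, -3.0)}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            find_clusters(np.zeros(4), 0.0, _chain_adjacency())


class TestPermutationTest:
    def test_large_shift_on_connected_block_is_significant(self, montage62, adjacency62, rng):
        pre = rng.normal(0.2, 0.01, (13, 62))
        post = pre.copy()
        block = [montage62.index_of(c) for c in ("F1", "Fz", "F2", "FC1", "FCz", "FC2")]
        post[:, block] += 0.05  # 5x the noise sd
        res = cluster_permutation_test(pre, post, adjacency62, n_perm=1000, seed=3)
        top = res.clusters[0]
        assert set(top.channels) >= {"F1", "Fz", "F2"}
        assert top.p_value <= 0.01

    def test_p_value_never_zero(self, adjacency62, rng):
        pre = rng.normal(0, 1, (8, 62))
        post = pre + 10.0  # overwhelming global shift
        res = cluster_permutation_test(pre, post, adjacency62, n_perm=500, seed=0)
        assert all(c.p_value >= 1 / 501 for c in res.clusters)

    def test_few_permutations_warn(self, adjacency62, rng):
        pre = rng.normal(0, 1, (5, 62))
        with pytest.warns(UserWarning, match="granularity"):
            cluster_permutation_test(pre, pre + rng.normal(0, 1, pre.shape),
                                     adjacency62, n_perm=50, seed=1)

    def test_seed_determinism(self, adjacency62, rng):
        pre = rng.normal(0, 1, (8, 62))
        post = pre + rng.normal(0.5, 1, pre.shape)
        a = cluster_permutation_test(pre, post, adjacency62, n_perm=300, seed=9)
        b = cluster_permutation_test(pre, post, adjacency62, n_perm=300, seed=9)
        assert [c.p_value for c in a.clusters] == [c.p_value for c in b.clusters]

    def test_swapping_conditions_negates_masses_keeps_p(self, adjacency62, rng):
        pre = rng.normal(0, 1, (9, 62))
        post = pre + rng.normal(0.4, 1, pre.shape)
        fwd = cluster_permutation_test(pre, post, adjacency62, n_perm=400, seed=5)
        rev = cluster_permutation_test(post, pre, adjacency62, n_perm=400, seed=5)
        fwd_masses = sorted(c.mass for c in fwd.clusters)
        rev_masses = sorted(-c.mass for c in rev.clusters)
        np.testing.assert_allclose(fwd_masses, rev_masses)
        assert sorted(c.p_value for c in fwd.clusters) == sorted(
            c.p_value for c in rev.clusters
        )


class TestExactEnumeration:
    def test_null_distribution_has_2_to_n_atoms(self, montage_small, rng):
        adj = build_adjacency(montage_small)
        pre = rng.normal(0, 1, (3, 8))
        post = pre + rng.normal(1.0, 1, pre.shape)
        res = exact_enumeration_test(pre, post, adj)
        assert len(res.null_max_mass) == 8  # 2^3

    def test_refuses_large_n(self, montage_small, rng):
        adj = build_adjacency(montage_small)
        pre = rng.normal(0, 1, (13, 8))
        with pytest.raises(ValueError, match="n <= 12"):
            exact_enumeration_test(pre, pre + 1.0, adj)

    def test_zero_differences_give_empty_result(self, montage_small):
        adj = build_adjacency(montage_small)
        x = np.tile(np.arange(8.0), (4, 1))
        res = exact_enumeration_test(x, x, adj)
        assert res.clusters == []

    def test_monte_carlo_converges_to_exact(self, montage_small, rng):
        """Monte-Carlo p within ±0.01 of the exact 2^n enumeration."""
        adj = build_adjacency(montage_small)
        for trial in range(3):
            pre = rng.normal(0, 1, (8, 8))
            post = pre + rng.normal(0.5, 1.0, pre.shape)
            exact = exact_enumeration_test(pre, post, adj)
            mc = cluster_permutation_test(pre, post, adj, n_perm=50000, seed=trial)
            assert [c.channels for c in exact.clusters] == [
                c.channels for c in mc.clusters
            ]
            for ce, cm in zip(exact.clusters, mc.clusters):
                assert abs(ce.p_value - cm.p_value) <= 0.01


def test_agreement_with_mne_reference(montage62, rng):
    """Observed clusters and Monte-Carlo p-values match MNE's independent
    sign-flip cluster permutation implementation."""
    mne_stats = pytest.importorskip("mne.stats")
    from scipy.sparse import csr_matrix

    labels = montage62.labels[:20]
    sub = Montage(labels=labels, coords=montage62.coords[:20])
    adj = build_adjacency(sub)
    pre = rng.normal(0, 1, (10, 20))
    post = pre + rng.normal(0.6, 1.0, pre.shape)
    res = cluster_permutation_test(pre, post, adj, n_perm=4000, seed=7)

    t_thresh = res.threshold
    t_obs, clusters, pvals, _ = mne_stats.permutation_cluster_1samp_test(
        post - pre,
        threshold=t_thresh,
        n_permutations=4000,
        adjacency=csr_matrix(adj.matrix),
        tail=0,
        seed=42,
        out_type="indices",
        verbose="ERROR",
    )
    np.testing.assert_allclose(t_obs, res.stat_map, atol=1e-8)
    ours = {
        frozenset(c.channels): (c.mass, c.p_value) for c in res.clusters
    }
    theirs = {}
    for inds, p in zip(clusters, pvals):
        chans = frozenset(labels[i] for i in np.atleast_1d(inds[0]))
        theirs[chans] = (float(t_obs[np.atleast_1d(inds[0])].sum()), float(p))
    assert set(ours) == set(theirs)
    for key in ours:
        assert ours[key][0] == pytest.approx(theirs[key][0], abs=1e-6)
        assert ours[key][1] == pytest.approx(theirs[key][1], abs=0.03)
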