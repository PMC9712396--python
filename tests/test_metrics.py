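import itertools
import math

import numpy as np
import pytest

from conftest import planted_block_matrix, random_connectivity
from ocsnet.community import Partition, louvain_partition
from ocsnet.connectome import ConnectivityMatrix
from ocsnet.metrics import (
    ThalamicNodeSet,
    all_partitions,
    exact_max_modularity,
    modularity,
    participation_coefficients,
    path_length_efficiency,
    small_worldness,
    thalamic_summary,
    weighted_clustering,
    within_module_z,
)


# ---------------------------------------------------------------- oracles
def modularity_oracle(w, memb, gamma):
    """Direct double sum over ordered node pairs."""
    two_w = w.sum()
    s = w.sum(axis=1)
    q = 0.0
    n = len(memb)
    for i in range(n):
        for j in range(n):
            if memb[i] == memb[j]:
                q += w[i, j] - gamma * s[i] * s[j] / two_w
    return q / two_w


def clustering_oracle(w):
    """Triple loop over geometric-mean triangle intensities (Onnela)."""
    n = w.shape[0]
    wn = w / w.max()
    cs = []
    for i in range(n):
        k = np.count_nonzero(w[i])
        if k < 2:
            cs.append(0.0)
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    tri += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1 / 3)
        cs.append(tri / (k * (k - 1)))
    return float(np.mean(cs))


def floyd_warshall_oracle(w):
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


# ------------------------------------------------------------- modularity
class TestModularity:
    def test_two_disconnected_cliques_give_half(self):
        w = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i, j in itertools.combinations(block, 2):
                w[i, j] = w[j, i] = 0.7
        m = ConnectivityMatrix(w, tuple("abcdef"))
        p = Partition(m.node_labels, np.array([0, 0, 0, 1, 1, 1]))
        assert modularity(m, p, gamma=1.0) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        m = random_connectivity(0, n=7)
        p = Partition(m.node_labels, np.zeros(7, dtype=int))
        assert modularity(m, p, gamma=1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        m = random_connectivity(seed, n=6)
        p = Partition(m.node_labels, np.array([0, 1, 2, 0, 1, 2]))
        for gamma in (1.0, 1.05, 1.3):
            assert modularity(m, p, gamma) == pytest.approx(
                modularity_oracle(m.w, p.membership, gamma), abs=1e-12
            )

    def test_empty_graph_rejected(self):
        m = ConnectivityMatrix(np.zeros((3, 3)), ("a", "b", "c"))
        p = Partition(m.node_labels, np.array([0, 0, 1]))
        with pytest.raises(ValueError):
            modularity(m, p)


# ------------------------------------------------- participation coefficient
class TestParticipation:
    def _two_module_graph(self, w_own, w_other):
        # node 0 in module 0 connects within (node 1) and across (node 2)
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w_own
        w[0, 2] = w[2, 0] = w_other
        w[2, 3] = w[3, 2] = 0.5
        m = ConnectivityMatrix(w, ("a", "b", "c", "d"))
        p = Partition(m.node_labels, np.array([0, 0, 1, 1]))
        return m, p

    def test_all_weight_within_module_gives_zero(self):
        m, p = self._two_module_graph(0.8, 0.0)
        assert participation_coefficients(m, p)[0] == pytest.approx(0.0)

    def test_equal_split_two_modules_gives_half(self):
        m, p = self._two_module_graph(0.4, 0.4)
        assert participation_coefficients(m, p)[0] == pytest.approx(0.5)

    def test_equal_split_five_modules(self):
        w = np.zeros((10, 10))
        for j in range(1, 6):
            w[0, j] = w[j, 0] = 0.2
        memb = np.array([0, 0, 1, 2, 3, 4, 1, 2, 3, 4])
        w[6, 7] = w[7, 6] = 0.1  # keep later modules from being strengthless
        w[8, 9] = w[9, 8] = 0.1
        m = ConnectivityMatrix(w, tuple(f"n{i}" for i in range(10)))
        p = Partition(m.node_labels, memb)
        # node 0: weight split equally across its own + 4 other modules
        assert participation_coefficients(m, p)[0] == pytest.approx(1 - 5 * 0.2**2)

    def test_single_community_avg_pc_is_zero(self):
        m = random_connectivity(3, n=6)
        p = Partition(m.node_labels, np.zeros(6, dtype=int))
        assert participation_coefficients(m, p).mean() == pytest.approx(0.0)


# ------------------------------------------------------ within-module Z
class TestWithinModuleZ:
    def test_identical_strengths_give_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = w[0, 2] = w[2, 0] = 0.4
        m = ConnectivityMatrix(w, ("a", "b", "c"))
        p = Partition(m.node_labels, np.zeros(3, dtype=int))
        np.testing.assert_allclose(within_module_z(m, p), 0.0)

    def test_strength_ladder_hand_computed(self):
        # within-module strengths (0.25, 0.5, 0.75): z = +-sqrt(3/2) and 0
        # with population SD
        w = np.zeros((3, 3))
        w[0, 2] = w[2, 0] = 0.25
        w[1, 2] = w[2, 1] = 0.5
        m = ConnectivityMatrix(w, ("a", "b", "c"))
        p = Partition(m.node_labels, np.zeros(3, dtype=int))
        z = within_module_z(m, p)
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        np.testing.assert_allclose(z, expected, atol=1e-8)

    def test_singleton_module_gets_zero(self):
        m = random_connectivity(2, n=4)
        p = Partition(m.node_labels, np.array([0, 0, 0, 1]))
        assert within_module_z(m, p)[3] == 0.0

    def test_zero_mean_within_modules(self):
        m = random_connectivity(5, n=12)
        p = Partition(m.node_labels, np.repeat([0, 1, 2], 4))
        z = within_module_z(m, p)
        for mod in range(3):
            assert z[p.membership == mod].mean() == pytest.approx(0.0, abs=1e-10)


# ----------------------------------------------------------- clustering
class TestClustering:
    def test_uniform_complete_graph_is_one(self):
        w = np.full((5, 5), 0.6)
        np.fill_diagonal(w, 0)
        m = ConnectivityMatrix(w, tuple("abcde"))
        assert weighted_clustering(m) == pytest.approx(1.0)

    def test_star_graph_is_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.5
        m = ConnectivityMatrix(w, tuple("abcde"))
        assert weighted_clustering(m) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_triple_loop_oracle(self, seed):
        m = random_connectivity(seed, n=4)
        assert weighted_clustering(m) == pytest.approx(clustering_oracle(m.w), abs=1e-12)

    def test_agrees_with_networkx_onnela(self):
        nx = pytest.importorskip("networkx")
        m = random_connectivity(11, n=7)
        g = nx.from_numpy_array(m.w)
        expected = np.mean(list(nx.clustering(g, weight="weight").values()))
        assert weighted_clustering(m) == pytest.approx(expected, abs=1e-10)


# ------------------------------------------------- path length / efficiency
class TestPathLength:
    def test_uniform_complete_graph(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0)
        m = ConnectivityMatrix(w, tuple("abcd"))
        L, E = path_length_efficiency(m)
        assert L == pytest.approx(2.0)
        assert E == pytest.approx(0.5)

    def test_path_graph_distance_adds(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        m = ConnectivityMatrix(w, ("a", "b", "c"))
        L, E = path_length_efficiency(m)
        # distances: ab=1, bc=1, ac=2 -> L = 4/3
        assert L == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_floyd_warshall_oracle(self, seed):
        m = random_connectivity(seed, n=6)
        d = floyd_warshall_oracle(m.w)
        off = ~np.eye(6, dtype=bool)
        L, E = path_length_efficiency(m)
        assert L == pytest.approx(d[off].mean(), abs=1e-10)
        assert E == pytest.approx((1 / d[off]).mean(), abs=1e-10)


# --------------------------------------------------------- small-worldness
class TestSmallWorldness:
    def test_identity_null_gives_exactly_one(self):
        m = random_connectivity(1, n=10)
        sigma = small_worldness(m, n_rand=1, null=lambda w, rng: w, seed=0)
        assert sigma == pytest.approx(1.0)

    def test_dense_random_graph_near_one(self):
        sigmas = [
            small_worldness(random_connectivity(s, n=30), n_rand=5, seed=s)
            for s in range(10)
        ]
        assert np.mean(sigmas) == pytest.approx(1.0, abs=0.15)

    def test_ring_lattice_with_shortcuts_exceeds_one(self):
        rng = np.random.default_rng(42)
        n = 40
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 0.9
        # 10% long-range shortcuts
        for _ in range(int(0.1 * n)):
            i, j = rng.integers(n, size=2)
            if i != j:
                w[i, j] = w[j, i] = 0.9
        m = ConnectivityMatrix(w, tuple(f"n{i}" for i in range(n)))
        assert small_worldness(m, n_rand=5, seed=0) > 1.0


# ------------------------------------------------------- thalamic summary
def _thal_setup(split_pairs: int):
    pairs = tuple(
        (f"sub{k}", f"sub{k}_L", f"sub{k}_R") for k in range(8)
    )
    labels = [lab for _, l, r in pairs for lab in (l, r)]
    memb = []
    for k in range(8):
        if k < split_pairs:
            memb += [0, 1]
        else:
            memb += [k % 2, k % 2]
    p = Partition(tuple(labels), np.array(memb)).canonicalized()
    values = {lab: float(i) for i, lab in enumerate(labels)}
    return values, ThalamicNodeSet(pairs), p


class TestThalamicSummary:
    def test_one_split_pair_yields_nine_values(self):
        values, ns, p = _thal_setup(split_pairs=1)
        out = thalamic_summary(values, ns, p)
        assert len(out) == 9

    def test_no_split_pairs_yields_eight(self):
        values, ns, p = _thal_setup(split_pairs=0)
        assert len(thalamic_summary(values, ns, p)) == 8

    def test_all_split_yields_sixteen(self):
        values, ns, p = _thal_setup(split_pairs=8)
        assert len(thalamic_summary(values, ns, p)) == 16

    def test_same_community_pair_averaged(self):
        values, ns, p = _thal_setup(split_pairs=1)
        out = thalamic_summary(values, ns, p)
        assert out["sub1"] == pytest.approx((values["sub1_L"] + values["sub1_R"]) / 2)
        assert out["sub0_L"] == values["sub0_L"]

    def test_missing_label_raises(self):
        values, ns, p = _thal_setup(split_pairs=1)
        del values["sub3_L"]
        with pytest.raises(KeyError):
            thalamic_summary(values, ns, p)


# ------------------------------------------------------ shared properties
class TestScaleInvariance:
    def test_metrics_invariant_to_weight_scaling(self):
        m = random_connectivity(9, n=12)
        scaled = ConnectivityMatrix(0.5 * m.w, m.node_labels)
        p = louvain_partition(m, gamma=1.0, seed=0)
        assert modularity(m, p, 1.05) == pytest.approx(modularity(scaled, p, 1.05), abs=1e-12)
        np.testing.assert_allclose(
            participation_coefficients(m, p), participation_coefficients(scaled, p), atol=1e-12
        )
        np.testing.assert_allclose(
            within_module_z(m, p), within_module_z(scaled, p), atol=1e-10
        )
        assert small_worldness(m, n_rand=3, seed=4) == pytest.approx(
            small_worldness(scaled, n_rand=3, seed=4), abs=1e-10
        )

    def test_louvain_beats_random_partition(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            m = random_connectivity(seed, n=10)
            p_opt = louvain_partition(m, gamma=1.0, seed=seed)
            memb = np.unique(rng.integers(0, 3, size=10), return_inverse=True)[1]
            p_rand = Partition(m.node_labels, memb)
            assert modularity(m, p_opt, 1.0) >= modularity(m, p_rand, 1.0) - 1e-12


def test_partition_enumeration_counts_bell_numbers():
    assert sum(1 for _ in all_partitions(range(4))) == 15
    assert sum(1 for _ in all_partitions(range(8))) == 4140


def test_exact_max_modularity_on_two_cliques():
    w = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i, j in itertools.combinations(block, 2):
            w[i, j] = w[j, i] = 0.7
    m = ConnectivityMatrix(w, tuple("abcdef"))
    q, p = exact_max_modularity(m, gamma=1.0)
    assert q == pytest.approx(0.5)
    assert p.K == 2
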