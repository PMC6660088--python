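import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmcnet import centrality as ce
from cmcnet.centrality import (
    ALL_MEASURES,
    NEIGHBOURHOOD_INCLUSION_PRESERVING,
    CentralityParams,
    NetworkKernels,
    centrality_profile,
    centrality_scores,
)
from cmcnet.graphio import Network
from cmcnet.synthnet import er_connected, star_graph, threshold_graph
from cmcnet.cmc import spearman
from cmcnet._ranks import tied_ranks

from conftest import net_from_edges
from oracles import (
    betweenness_exhaustive,
    current_flow_betweenness_kirchhoff,
    expm_series,
    random_connected_graph,
)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

class TestKernels:
    def test_distances_path_triangle(self, p3, k3):
        assert ce.shortest_path_distances(p3)[0, 2] == 2
        D = ce.shortest_path_distances(k3)
        assert np.all(D[~np.eye(3, dtype=bool)] == 1)

    def test_distances_weighted_inverse_length(self):
        A = np.array([[0.0, 2.0], [2.0, 0.0]])
        net = Network(A, ("a", "b"), weighted=True)
        assert ce.shortest_path_distances(net)[0, 1] == 0.5

    def test_spectral_star_and_cycle(self, star3, c4):
        sd = ce.spectral_data(star3)
        assert sd.lambda1 == pytest.approx(np.sqrt(3), abs=1e-12)
        assert sd.lambda2 == pytest.approx(0.0, abs=1e-12)
        sd = ce.spectral_data(c4)
        assert sd.lambda1 == pytest.approx(2.0, abs=1e-12)
        assert sd.lambda2 == pytest.approx(0.0, abs=1e-12)

    def test_spectral_k2_vector(self, k2):
        sd = ce.spectral_data(k2)
        assert sd.lambda1 == pytest.approx(1.0)
        np.testing.assert_allclose(sd.leading_vector, [1 / np.sqrt(2)] * 2)

    def test_walk_kernel_matches_series(self, k2, p3):
        for net in (k2, p3):
            wk = ce.walk_kernel(net)
            np.testing.assert_allclose(wk.expA, expm_series(net.adjacency),
                                       rtol=1e-12)
        assert ce.walk_kernel(k2).expA[0, 0] == pytest.approx(np.cosh(1.0))
        assert ce.walk_kernel(p3).expA[0, 2] == pytest.approx(
            (np.cosh(np.sqrt(2)) - 1) / 2)

    def test_walk_kernel_deletion_bounds(self, p3):
        wk = ce.walk_kernel(p3, with_deletions=True)
        assert wk.norm_constant == 2.0
        for i in range(3):
            assert np.all(wk.deleted_expA[i] <= wk.expA + 1e-12)

    def test_mfpt_hand_values(self, k2, p3, k3):
        np.testing.assert_allclose(ce.mfpt_matrix(k2),
                                   np.array([[0.0, 1.0], [1.0, 0.0]]))
        H = ce.mfpt_matrix(p3)
        assert H[1, 0] == pytest.approx(3.0)
        assert H[2, 0] == pytest.approx(4.0)
        assert H[0, 1] == pytest.approx(1.0)
        H3 = ce.mfpt_matrix(k3)
        np.testing.assert_allclose(H3[~np.eye(3, dtype=bool)], 2.0)

    def test_mfpt_dominates_distance(self):
        net = er_connected(12, 20, seed=3)
        H = ce.mfpt_matrix(net)
        D = ce.shortest_path_distances(net)
        assert np.all(H >= D - 1e-9)


# ---------------------------------------------------------------------------
# Measure values on hand-solved fixtures
# ---------------------------------------------------------------------------

P3_EXPECTED = {
    "DC": [1.0, 2.0, 1.0],
    "BC": [0.0, 1.0, 0.0],
    "CC": [1.0, 1.5, 1.0],
    "LC": [-1 / 3, 1 / 3, -1 / 3],
    "LAPC": [6.0, 10.0, 6.0],
    "RWCC": [3 / 7, 1.5, 3 / 7],
    "BridC": [0.0, 0.25, 0.0],
    "HC": [1.0, 1.0, 1.0],
}


@pytest.mark.parametrize("measure,expected", sorted(P3_EXPECTED.items()))
def test_measures_on_path(p3, measure, expected):
    np.testing.assert_allclose(centrality_scores(p3, measure), expected,
                               rtol=1e-12, atol=1e-12)


class TestMeasureValues:
    def test_eigenvector_star(self, star3):
        ec = centrality_scores(star3, "EC")
        assert ec[0] == pytest.approx(1 / np.sqrt(2), abs=1e-10)
        np.testing.assert_allclose(ec[1:], 1 / np.sqrt(6), atol=1e-10)

    def test_subgraph_and_total_communicability_k2(self, k2):
        np.testing.assert_allclose(centrality_scores(k2, "SC"),
                                   np.cosh(1.0), rtol=1e-12)
        np.testing.assert_allclose(centrality_scores(k2, "TCC"),
                                   np.e, rtol=1e-12)

    def test_information_k2(self, k2):
        np.testing.assert_allclose(centrality_scores(k2, "IC"), 2.0, rtol=1e-12)

    def test_katz_k2(self, k2):
        np.testing.assert_allclose(centrality_scores(k2, "KC"), 20 / 3,
                                   rtol=1e-12)

    def test_katz_fixed_point_iteration_oracle(self):
        net = er_connected(10, 20, seed=5)
        params = CentralityParams()
        kc = centrality_scores(net, "KC", params)
        lam1 = ce.spectral_data(net).lambda1
        alpha = params.katz_alpha_fraction / lam1
        x = np.ones(net.n_nodes)
        for _ in range(500):
            x = alpha * net.adjacency @ x + 1.0
        np.testing.assert_allclose(kc, x, rtol=1e-8)

    def test_pagerank_star(self, star3):
        pr = centrality_scores(star3, "PR")
        assert pr[0] == pytest.approx(0.47973, abs=1e-5)
        np.testing.assert_allclose(pr[1:], 0.17342, atol=1e-5)
        assert pr.sum() == pytest.approx(1.0)

    def test_pagerank_power_iteration_oracle(self):
        net = er_connected(12, 24, seed=8)
        pr = centrality_scores(net, "PR")
        n = net.n_nodes
        alpha, beta = 0.85, 0.15 / 12
        M = net.adjacency / net.strengths[None, :]
        x = np.full(n, 1.0 / n)
        for _ in range(1000):
            x = alpha * M @ x + beta
        x /= x.sum()
        np.testing.assert_allclose(pr, x, rtol=1e-10)

    def test_star_hub_maximal_on_dc_cc_bc(self):
        net = star_graph(6)
        for m in ("DC", "CC", "BC"):
            scores = centrality_scores(net, m)
            assert np.argmax(scores) == 0

    def test_hindex_examples(self):
        # hub of K_{1,4}: 4 neighbours of degree 1 -> h = 1
        net = star_graph(4)
        hc = centrality_scores(net, "HC")
        assert hc[0] == 1.0
        # K4: 3 neighbours of degree 3 -> h = 3
        k4 = net_from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)
        np.testing.assert_array_equal(centrality_scores(k4, "HC"), 3.0)

    def test_unknown_measure_raises(self, p3):
        with pytest.raises(ValueError, match="unknown measure"):
            centrality_scores(p3, "XYZ")

    def test_katz_alpha_fraction_bounds(self):
        with pytest.raises(ValueError):
            CentralityParams(katz_alpha_fraction=1.0)
        with pytest.raises(ValueError):
            CentralityParams(pagerank_damping=0.0)


class TestCommunicabilityBetweenness:
    def test_interior_of_path_is_one(self, p3):
        cbc = ce.communicability_betweenness(p3)
        assert cbc[1] == pytest.approx(1.0, abs=1e-10)

    def test_k2_raises_empty_sum(self, k2):
        with pytest.raises(ValueError):
            ce.communicability_betweenness(k2)

    def test_bounded_in_unit_interval(self):
        for seed in range(3):
            net = er_connected(12, 25, seed=seed)
            cbc = ce.communicability_betweenness(net)
            assert np.all(cbc >= -1e-12) and np.all(cbc <= 1 + 1e-12)

    def test_matches_deletion_kernel_series_oracle(self):
        net = er_connected(8, 14, seed=2)
        n = net.n_nodes
        cbc = ce.communicability_betweenness(net)
        G = expm_series(net.adjacency, terms=40)
        expected = np.zeros(n)
        for i in range(n):
            Ai = net.adjacency.copy()
            Ai[i, :] = 0
            Ai[:, i] = 0
            Gi = expm_series(Ai, terms=40)
            for p in range(n):
                for q in range(n):
                    if p == q or p == i or q == i:
                        continue
                    expected[i] += (G[p, q] - Gi[p, q]) / G[p, q]
        expected /= (n - 1) ** 2 - (n - 1)
        np.testing.assert_allclose(cbc, expected, rtol=1e-8)

    def test_size_cap(self, p3):
        with pytest.raises(ValueError, match="cbc_max_nodes"):
            ce.communicability_betweenness(p3, CentralityParams(cbc_max_nodes=2))


class TestCurrentFlowBetweenness:
    def test_k2_endpoint_convention(self, k2):
        np.testing.assert_allclose(ce.current_flow_betweenness(k2), 1.0)

    def test_path_values(self, p3):
        np.testing.assert_allclose(ce.current_flow_betweenness(p3),
                                   [2 / 3, 1.0, 2 / 3], rtol=1e-12)

    def test_matches_kirchhoff_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            A = random_connected_graph(8, 0.35, rng)
            net = Network(A, tuple(str(i) for i in range(8)))
            got = ce.current_flow_betweenness(net)
            want = current_flow_betweenness_kirchhoff(A)
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_tree_ranking_matches_shortest_path_bc(self):
        import networkx as nx

        for seed in range(5):
            T = nx.random_labeled_tree(12, seed=seed)
            net = Network.from_networkx(T)
            rwbc = ce.current_flow_betweenness(net)
            bc = centrality_scores(net, "BC")
            assert np.array_equal(tied_ranks(rwbc), tied_ranks(bc))


class TestParticipationCoefficient:
    def test_own_module_only(self):
        net = net_from_edges([(0, 1), (0, 2), (1, 2)], 3)
        pc = ce.participation_coefficient(net, np.array([1, 1, 1]))
        np.testing.assert_allclose(pc, 0.0)

    def test_even_split_half(self):
        # node 0 with 2 neighbours in each of two modules
        net = net_from_edges([(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (3, 4)], 5)
        pc = ce.participation_coefficient(net, np.array([1, 1, 1, 2, 2]))
        assert pc[0] == pytest.approx(0.5)

    def test_one_three_split(self):
        net = net_from_edges([(0, 1), (0, 2), (0, 3), (0, 4),
                              (2, 3), (3, 4), (2, 4)], 5)
        pc = ce.participation_coefficient(net, np.array([1, 1, 2, 2, 2]))
        assert pc[0] == pytest.approx(1 - (1 / 16 + 9 / 16))

    def test_partition_must_cover(self, p3):
        with pytest.raises(ValueError):
            ce.participation_coefficient(p3, np.array([1, 1]))


# ---------------------------------------------------------------------------
# Profiles and structural invariants
# ---------------------------------------------------------------------------

class TestProfile:
    def test_default_profile_has_17_columns(self):
        net = er_connected(15, 30, seed=1)
        prof = centrality_profile(net, partition=np.ones(15, dtype=int))
        assert prof.scores.shape == (15, 17)
        assert list(prof.scores.columns) == list(ALL_MEASURES)
        assert np.isfinite(prof.scores.to_numpy()).all()

    def test_failed_measure_yields_nan_column(self, caplog):
        import logging

        net = er_connected(10, 20, seed=4)
        with caplog.at_level(logging.WARNING):
            prof = centrality_profile(net)  # no partition: PC must fail
        assert prof.scores["PC"].isna().all()
        assert not prof.scores["DC"].isna().any()
        assert any("PC" in r.message for r in caplog.records)

    def test_relabeling_permutes_all_columns_identically(self):
        rng = np.random.default_rng(11)
        net = er_connected(10, 22, seed=11)
        perm = rng.permutation(10)
        P = np.eye(10)[perm]
        permuted = Network(P @ net.adjacency @ P.T,
                           tuple(net.node_labels[i] for i in perm))
        part = np.array([1, 1, 1, 2, 2, 2, 2, 1, 2, 1])
        prof1 = centrality_profile(net, partition=part)
        prof2 = centrality_profile(permuted, partition=part[perm])
        for m in ALL_MEASURES:
            np.testing.assert_allclose(
                prof1.scores[m].to_numpy()[perm], prof2.scores[m].to_numpy(),
                rtol=1e-8, atol=1e-10,
            )

    def test_vertex_transitive_graphs_constant(self, k4):
        import networkx as nx

        c5 = Network.from_networkx(nx.cycle_graph(5))
        for net in (k4, c5):
            prof = centrality_profile(
                net, partition=np.ones(net.n_nodes, dtype=int))
            for m in ALL_MEASURES:
                col = prof.scores[m].to_numpy()
                assert np.allclose(col, col[0], rtol=1e-8, atol=1e-10), m


def _dominates(A, i, j):
    ni = set(np.flatnonzero(A[i] > 0)) - {j}
    nj = set(np.flatnonzero(A[j] > 0)) - {i}
    return nj <= ni


class TestNeighbourhoodInclusion:
    """Dominance (N(j)\\{i} subset of N(i)\\{j}) must imply score_i >= score_j
    for the neighbourhood-inclusion-preserving measures."""

    def test_dominance_implies_ordering(self):
        rng = np.random.default_rng(21)
        params = CentralityParams(
            measure_list=NEIGHBOURHOOD_INCLUSION_PRESERVING)
        for _ in range(20):
            n = int(rng.integers(5, 13))
            A = random_connected_graph(n, 0.35, rng)
            net = Network(A, tuple(str(i) for i in range(n)))
            prof = centrality_profile(net, params).scores
            for i in range(n):
                for j in range(n):
                    if i == j or not _dominates(A, i, j):
                        continue
                    for m in prof.columns:
                        assert prof[m].iloc[i] >= prof[m].iloc[j] - 1e-9, (
                            f"{m}: node {i} dominates {j} but scores invert"
                        )

    def test_threshold_graph_concordance_excluding_betweenness(self):
        """On threshold graphs all non-betweenness inclusion-preserving
        measures induce identical rankings including ties; betweenness
        agrees as a weak order (no strict inversions)."""
        params = CentralityParams(
            measure_list=NEIGHBOURHOOD_INCLUSION_PRESERVING)
        for seed in range(5):
            net = threshold_graph(n=40, seed=seed)
            prof = centrality_profile(net, params).scores
            ranks = {m: tied_ranks(prof[m].to_numpy()) for m in prof.columns}
            for m in prof.columns:
                if m == "BC":
                    continue
                assert np.array_equal(ranks[m], ranks["DC"]), m
            # BC: zero plateau allowed, but never a strict inversion vs DC
            dd = np.sign(np.subtract.outer(ranks["DC"], ranks["DC"]))
            db = np.sign(np.subtract.outer(ranks["BC"], ranks["BC"]))
            assert not np.any(dd * db < 0)


class TestStochasticProperties:
    def test_rwcc_ic_highly_correlated_on_er(self):
        failures = 0
        for seed in range(20):
            net = er_connected(50, int(0.1 * 50 * 49 / 2), seed=seed)
            rwcc = centrality_scores(net, "RWCC")
            ic = centrality_scores(net, "IC")
            if spearman(rwcc, ic) <= 0.8:
                failures += 1
        assert failures <= 1


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_weighted_measures_reduce_to_unweighted_at_unit_weights(seed):
    """A 'weighted' network whose weights are all 1 must score identically
    to its unweighted twin on every measure."""
    rng = np.random.default_rng(seed)
    A = random_connected_graph(8, 0.4, rng)
    unweighted = Network(A, tuple(str(i) for i in range(8)), weighted=False)
    weighted = Network(A, tuple(str(i) for i in range(8)), weighted=True)
    part = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    for m in ALL_MEASURES:
        a = centrality_scores(unweighted, m, partition=part)
        b = centrality_scores(weighted, m, partition=part)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)
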