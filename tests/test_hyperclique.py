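"""Hyperclique code construction: subsets, codewords, S-membership, decoding."""

import math

import numpy as np
import pytest

from hopflow import hyperclique as hc
from hopflow.network import corrupt


@pytest.fixture(scope="module")
def code64():
    return hc.analytic_weights(64, 1)


class TestSubsetsAndAdjacency:
    @pytest.mark.parametrize("v, d, expected", [(8, 1, 28), (4, 1, 6), (12, 2, 220)])
    def test_node_counts(self, v, d, expected):
        assert len(hc.node_subsets(v, d)) == expected

    def test_colex_order_and_bijection(self):
        subs = hc.node_subsets(5, 1)
        assert subs[:4] == [(0, 1), (0, 2), (1, 2), (0, 3)]
        assert len(set(subs)) == len(subs)

    def test_rejects_too_small_vertex_set(self):
        with pytest.raises(ValueError):
            hc.node_subsets(2, 1)

    @pytest.mark.parametrize(
        "a, b, expected",
        [((1, 2), (2, 3), True), ((1, 2), (3, 4), False), ((1, 2), (1, 2), False)],
    )
    def test_adjacent_pairs(self, a, b, expected):
        assert hc.adjacent(a, b) is expected

    def test_adjacent_triples_share_d_vertices(self):
        assert hc.adjacent((0, 1, 2), (0, 1, 3))
        assert not hc.adjacent((0, 1, 2), (0, 3, 4))

    def test_neighbour_count_identity(self):
        """w + w' = (d+1)(v - (d+1)) for every node."""
        for v, d in [(8, 1), (10, 2)]:
            code = hc.CodeNetwork(v, d, 0.1)
            degrees = code.adjacency.sum(axis=1)
            assert np.all(degrees == (d + 1) * (v - (d + 1)))


class TestEncode:
    def test_d1_vertex_subset_gives_clique_edges(self):
        code = hc.CodeNetwork(4, 1, 0.1)
        G = hc.HypergraphSpec.from_edges(4, 1, [(1,), (2,), (3,)])
        ones = {code.subsets[i] for i in np.flatnonzero(code.encode(G))}
        assert ones == {(1, 2), (1, 3), (2, 3)}

    def test_d2_triangle_gives_single_node(self):
        code = hc.CodeNetwork(4, 2, 0.1)
        G = hc.HypergraphSpec.from_edges(4, 2, [(1, 2), (1, 3), (2, 3)])
        x = code.encode(G)
        assert x.sum() == 1
        assert code.subsets[int(np.flatnonzero(x)[0])] == (1, 2, 3)

    def test_empty_hypergraph_encodes_to_zero(self):
        code = hc.CodeNetwork(6, 1, 0.1)
        G = hc.HypergraphSpec.from_edges(6, 1, [])
        assert code.encode(G).sum() == 0

    def test_mismatched_parameters_rejected(self):
        code = hc.CodeNetwork(6, 1, 0.1)
        with pytest.raises(ValueError):
            code.encode(hc.HypergraphSpec.from_edges(7, 1, [(0,)]))


class TestWCounts:
    def test_full_hypergraph_saturates(self):
        v, d = 8, 1
        code = hc.CodeNetwork(v, d, 0.1)
        G = hc.HypergraphSpec.from_edges(v, d, [(u,) for u in range(v)])
        assert np.all(code.w_counts(G) == (d + 1) * (v - d - 1))

    def test_empty_hypergraph_zero(self):
        code = hc.CodeNetwork(8, 1, 0.1)
        assert np.all(code.w_counts(hc.HypergraphSpec.from_edges(8, 1, [])) == 0)

    def test_mean_w_of_complete_nodes(self, rng):
        """Complete pairs at d=1, v=64: E[w] = (d+1)(v-d-1)/2^d = 62
        (the v->infinity form of this expectation is (d+1)v/2^d)."""
        code = hc.analytic_weights(64, 1)
        vals = []
        for _ in range(30):
            G = hc.random_hypergraph(64, 1, rng)
            comp = code.complete_mask(G)
            if comp.any():
                vals.append(code.w_counts(G)[comp].mean())
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(mean - 62.0) < 4 * max(se, 1.0)


class TestSetS:
    def test_random_hypergraphs_frequently_accepted(self, rng, code64):
        acc = sum(code64.in_S(hc.random_hypergraph(64, 1, rng)) for _ in range(60))
        assert acc >= 20  # typical graphs land in S with decent frequency

    def test_full_hypergraph_rejected(self, code64):
        G = hc.HypergraphSpec.from_edges(64, 1, [(u,) for u in range(64)])
        assert not code64.in_S(G)

    def test_empty_hypergraph_rejected(self, code64):
        assert not code64.in_S(hc.HypergraphSpec.from_edges(64, 1, []))

    def test_tolerance_schedule_in_unit_interval(self):
        tol = hc.SToleranceParams()
        eps_vals = [tol.epsilon(v) for v in (8, 32, 64, 256, 4096)]
        assert all(0.0 < e < 1.0 for e in eps_vals)
        assert eps_vals == sorted(eps_vals, reverse=True)


class TestAnalyticWeights:
    def test_formula_value(self):
        assert hc.analytic_weight(64, 1, 1.0) == pytest.approx(4.0 / 192.0)

    def test_fixed_point_margin_ratio(self):
        """(d+1)/2^d * x * v / z = 2(d+1)/(2d+1) > 1 for every d >= 1."""
        for d in range(1, 6):
            x = hc.analytic_weight(100, d, 1.0)
            assert (d + 1) / 2**d * x * 100 / 1.0 == pytest.approx(2 * (d + 1) / (2 * d + 1))
            assert (d + 1) / 2**d * x * 100 > 1.0

    def test_codewords_of_S_are_fixed_points(self, rng, code64):
        for _ in range(20):
            G = hc.sample_hypergraph_in_S(code64, rng)
            x = code64.encode(G)
            assert np.array_equal(code64.decode(x, "single_sync"), x)
            assert code64.to_network().is_fixed_point(x)


class TestRobustnessIndex:
    def test_printed_value_d1(self):
        assert hc.robustness_index(1, "constructed") == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "d, variant, expected",
        [(2, "constructed", 1 / 8), (1, "mef_trained", 1 / 4), (2, "mef_trained", 1 / 16)],
    )
    def test_closed_forms(self, d, variant, expected):
        assert hc.robustness_index(d, variant) == pytest.approx(expected)

    def test_constructed_dominates_mef_variant(self):
        for d in range(1, 8):
            assert hc.robustness_index(d, "constructed") >= hc.robustness_index(d, "mef_trained")

    def test_invalid_d(self):
        with pytest.raises(ValueError):
            hc.robustness_index(0)


class TestRandomHypergraph:
    def test_mean_edge_count(self, rng):
        v, d = 20, 2
        total = math.comb(v, d)
        counts = [len(hc.random_hypergraph(v, d, rng).hyperedges) for _ in range(100)]
        se = np.sqrt(total * 0.25 / 100)
        assert abs(np.mean(counts) - total / 2) < 4 * se

    def test_complete_node_fraction(self, rng, code64):
        """About 2^{-(d+1)} of the nodes are hypercliques."""
        fracs = [
            code64.complete_mask(hc.random_hypergraph(64, 1, rng)).mean()
            for _ in range(30)
        ]
        assert abs(np.mean(fracs) - 0.25) < 0.02

    def test_seeded_reproducibility(self):
        g1 = hc.random_hypergraph(16, 2, np.random.default_rng(42))
        g2 = hc.random_hypergraph(16, 2, np.random.default_rng(42))
        assert g1 == g2


class TestDecode:
    def test_identity_on_codeword_at_zero_noise(self, rng, code64):
        G = hc.sample_hypergraph_in_S(code64, rng)
        x = code64.encode(G)
        y = corrupt(x, 0.0, rng)
        assert np.array_equal(code64.decode(y, "single_sync"), x)
        assert np.array_equal(code64.decode(y, "converge"), x)

    def test_unknown_mode(self, code64):
        with pytest.raises(ValueError):
            code64.decode(np.zeros(code64.n), "both")

    def test_small_corruption_single_pass_recovery(self, rng, code64):
        hits = 0
        for _ in range(25):
            G = hc.sample_hypergraph_in_S(code64, rng)
            x = code64.encode(G)
            hits += np.array_equal(code64.decode(corrupt(x, 0.05, rng)), x)
        assert hits >= 20  # p = 0.05 is far below the d=1 index alpha = 1/2


class TestRobustnessSim:
    def test_perfect_recovery_at_zero(self, rng):
        tab = hc.robustness_sim(32, 1, [0.0], trials=5, rng=rng)
        assert tab.loc[0, "recovery_fraction"] == 1.0

    def test_monotone_in_corruption(self, rng):
        tab = hc.robustness_sim(64, 1, [0.0, 0.1, 0.3], trials=15, rng=rng)
        fr = tab["recovery_fraction"].to_numpy()
        assert fr[0] >= fr[1] >= fr[2]

    def test_rejection_cap_error(self, rng):
        # d=2 at v=12 is far below the asymptotic regime: nothing enters S
        code = hc.analytic_weights(12, 2)
        with pytest.raises(RuntimeError, match="tolerance"):
            hc.sample_hypergraph_in_S(code, rng, cap=50)


class TestWeightRatioRecovery:
    def test_memory_count_grows_with_v(self, rng):
        """Distinct S-codewords multiply rapidly with the vertex count."""
        counts = {}
        for v in (16, 24):
            code = hc.analytic_weights(v, 1)
            words = {
                code.encode(hc.sample_hypergraph_in_S(code, rng)).tobytes()
                for _ in range(40)
            }
            counts[v] = len(words)
        assert counts[24] >= counts[16] >= 35  # essentially all draws distinct

    def test_ef_minimum_matches_analytic_weight(self, rng):
        x_hat, z, ratio = hc.fit_weight_ratio(32, 1, n_samples=30, rng=rng)
        assert ratio == pytest.approx(hc.analytic_weight(32, 1), rel=0.15)
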