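"""Unit and property tests for the directed network and diffusion core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drgcn import (
    AlignmentError,
    DegenerateNetworkError,
    GeneCancerWeights,
    InvalidInputError,
    PropagationConfig,
    RegulationNetwork,
    add_self_loops,
    build_degree_operator,
    extract_weights,
    propagate_layer,
)
from drgcn.network import (
    read_edge_list,
    read_gene_cancer,
    write_edge_list,
    write_gene_cancer,
)

from conftest import random_digraph


def brute_force_layer(adj, diag, features):
    """Independent per-node double-loop aggregation oracle."""
    G, K = features.shape
    out = np.zeros((G, K))
    for i in range(G):
        for j in range(G):
            if adj[i, j]:
                out[i] += features[j]
        out[i] *= diag[i]
    return out


class TestSelfLoops:
    def test_empty_graph_becomes_identity(self):
        net = RegulationNetwork(list("abc"), np.zeros((3, 3)))
        assert np.array_equal(add_self_loops(net).adjacency, np.eye(3))

    def test_single_edge(self):
        net = RegulationNetwork(["a", "b"], np.array([[0, 1], [0, 0]]))
        assert np.array_equal(
            add_self_loops(net).adjacency, np.array([[1, 1], [0, 1]])
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 8), st.integers(0, 2**32 - 1))
    def test_saturates_at_one(self, n, seed):
        # oracle: elementwise max(A, I), so pre-existing self-loops stay 1
        rng = np.random.default_rng(seed)
        adj = (rng.random((n, n)) < 0.4).astype(np.uint8)
        net = RegulationNetwork([f"g{i}" for i in range(n)], adj)
        aug = add_self_loops(net).adjacency
        assert np.array_equal(aug, np.maximum(adj, np.eye(n, dtype=np.uint8)))
        assert set(np.unique(aug)) <= {0, 1}

    def test_rejects_non_binary(self):
        with pytest.raises(InvalidInputError, match=r"\(0, 1\)"):
            RegulationNetwork(["a", "b"], np.array([[0, 2], [0, 0]]))

    def test_rejects_non_square(self):
        with pytest.raises(InvalidInputError, match="square"):
            RegulationNetwork(["a", "b"], np.zeros((2, 3)))

    def test_rejects_duplicate_genes(self):
        with pytest.raises(InvalidInputError, match="duplicate"):
            RegulationNetwork(["a", "a"], np.zeros((2, 2)))


class TestDegreeOperator:
    def test_symmetric_triangle(self, triangle_network):
        op = build_degree_operator(triangle_network, mode="in")
        assert np.allclose(op.diag_values, [1 / 3, 1 / 3, 1 / 3])

    def test_chain_in_degrees(self, chain_network):
        aug = add_self_loops(chain_network)
        op = build_degree_operator(aug, mode="in")
        assert np.allclose(op.diag_values, [1.0, 0.5, 0.5])

    def test_raw_chain_signed_fallback(self):
        # raw 2-node chain: node a has in-degree 0, |E| = 1
        net = RegulationNetwork(["a", "b"], np.array([[0, 1], [0, 0]]))
        op = build_degree_operator(net, mode="in", allow_raw=True)
        assert np.allclose(op.diag_values, [-1.0, 1.0])

    def test_edgeless_raw_network_is_degenerate(self):
        net = RegulationNetwork(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(DegenerateNetworkError):
            build_degree_operator(net, mode="in", allow_raw=True)

    def test_requires_self_loops_unless_raw(self, chain_network):
        with pytest.raises(InvalidInputError, match="self-loops"):
            build_degree_operator(chain_network)

    def test_full_rank_on_random_digraphs(self):
        # augmented and raw operators both keep a nonzero diagonal
        rng = np.random.default_rng(42)
        for _ in range(100):
            G = int(rng.integers(2, 51))
            net = random_digraph(rng, G, 0.1)
            mode = "in" if rng.random() < 0.5 else "out"
            if net.n_edges > 0 and rng.random() < 0.5:
                op = build_degree_operator(net, mode=mode, allow_raw=True)
            else:
                op = build_degree_operator(add_self_loops(net), mode=mode)
            assert np.all(op.diag_values != 0)
            d = np.diag(op.diag_values)
            assert np.isfinite(np.linalg.cond(d))
            assert np.allclose(d @ np.diag(1 / op.diag_values), np.eye(G))

    def test_undirected_reduction_row_stochastic(self):
        # on symmetric graphs, in and out modes coincide and D^-1 A~ has unit rows
        rng = np.random.default_rng(7)
        for _ in range(20):
            G = int(rng.integers(2, 30))
            adj = (rng.random((G, G)) < 0.3).astype(np.uint8)
            adj = np.maximum(adj, adj.T)
            net = add_self_loops(RegulationNetwork([f"g{i}" for i in range(G)], adj))
            op_in = build_degree_operator(net, mode="in")
            op_out = build_degree_operator(net, mode="out")
            assert np.array_equal(op_in.diag_values, op_out.diag_values)
            walk = op_in.diag_values[:, None] * net.adjacency
            assert np.allclose(walk.sum(axis=1), 1.0, atol=1e-12)

    def test_global_norm_option(self, triangle_network):
        op = build_degree_operator(triangle_network, mode="in", global_norm=True)
        assert np.allclose(op.diag_values, 1 / 9)


class TestPropagateLayer:
    def test_identity_network_is_identity(self):
        net = RegulationNetwork(list("abcd"), np.eye(4))
        op = build_degree_operator(net, mode="in")
        h = np.arange(12.0).reshape(4, 3)
        assert np.allclose(propagate_layer(h, net, op), h)

    def test_row_stochastic_preserves_constants(self, triangle_network):
        op = build_degree_operator(triangle_network, mode="in")
        h = np.ones((3, 1))
        assert np.allclose(propagate_layer(h, triangle_network, op), 1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            G = int(rng.integers(2, 21))
            K = int(rng.integers(1, 6))
            net = add_self_loops(random_digraph(rng, G, 0.3))
            op = build_degree_operator(net, mode="in")
            h = rng.normal(size=(G, K))
            expected = brute_force_layer(net.adjacency, op.diag_values, h)
            assert np.allclose(propagate_layer(h, net, op), expected, atol=1e-12)

    def test_relu_activation(self):
        net = RegulationNetwork(["a"], np.eye(1))
        op = build_degree_operator(net)
        out = propagate_layer(np.array([[-2.0]]), net, op, activation="relu")
        assert out[0, 0] == 0.0

    def test_layer_weight_applied(self, triangle_network):
        op = build_degree_operator(triangle_network)
        h = np.ones((3, 2))
        w = np.array([[2.0, 0.0], [0.0, 3.0]])
        out = propagate_layer(h, triangle_network, op, layer_weight=w)
        assert np.allclose(out, [[2.0, 3.0]] * 3)

    def test_shape_mismatch_reports_shapes(self, triangle_network):
        op = build_degree_operator(triangle_network)
        with pytest.raises(InvalidInputError, match=r"\(3, K\)"):
            propagate_layer(np.ones((4, 2)), triangle_network, op)


class TestExtractWeights:
    def test_zero_layers_returns_initial(self, chain_network):
        h0 = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        out = extract_weights(chain_network, h0, PropagationConfig(n_layers=0))
        assert np.array_equal(out, h0)

    def test_disconnected_nodes_keep_weights(self):
        net = RegulationNetwork(list("abc"), np.zeros((3, 3)))
        h0 = np.array([[1.0], [0.5], [0.0]])
        for layers in (1, 2, 5):
            out = extract_weights(net, h0, PropagationConfig(n_layers=layers))
            assert np.allclose(out, h0)

    def test_chain_one_hot_single_step(self, chain_network):
        # one propagation step by hand: g2 averages {self=0, target g3=1} -> 1/2;
        # g3 averages {self=1} -> 1/2; g1 sees only zeros
        h0 = np.array([[0.0], [0.0], [1.0]])
        out = extract_weights(chain_network, h0, PropagationConfig(n_layers=1))
        assert np.allclose(out.ravel(), [0.0, 0.5, 0.5], atol=1e-12)

    def test_linearity_under_identity_activation(self):
        rng = np.random.default_rng(3)
        net = random_digraph(rng, 15, 0.2)
        h0 = rng.random((15, 4))
        cfg = PropagationConfig(n_layers=3)
        base = extract_weights(net, h0, cfg)
        scaled = extract_weights(net, 2.5 * h0, cfg)
        assert np.allclose(scaled, 2.5 * base, atol=1e-12)

    def test_locality_reverse_hops(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            G = 20
            net = random_digraph(rng, G, 0.1)
            hot = int(rng.integers(G))
            h0 = np.zeros((G, 1))
            h0[hot] = 1.0
            for L in (1, 2, 3):
                out = extract_weights(net, h0, PropagationConfig(n_layers=L))
                # reachable-within-L along reversed edges (plus the hot node)
                reach = {hot}
                frontier = {hot}
                for _ in range(L):
                    frontier = {
                        i
                        for j in frontier
                        for i in np.flatnonzero(net.adjacency[:, j])
                    }
                    reach |= frontier
                support = set(np.flatnonzero(out.ravel() != 0))
                assert support <= reach

    def test_gene_order_mismatch(self, chain_network):
        w = GeneCancerWeights(["g1", "g3", "g2"], ["c"], np.zeros((3, 1)))
        with pytest.raises(AlignmentError, match="g2"):
            extract_weights(chain_network, w, PropagationConfig())

    def test_gene_cancer_weights_round_trip(self, chain_network):
        w = GeneCancerWeights(["g1", "g2", "g3"], ["c1"], np.array([[0.0], [0.0], [1.0]]))
        out = extract_weights(chain_network, w, PropagationConfig(n_layers=1))
        assert isinstance(out, GeneCancerWeights)
        assert out.cancers == ["c1"]
        assert np.allclose(out.values.ravel(), [0.0, 0.5, 0.5])


class TestPropagationConfig:
    def test_rejects_negative_layers(self):
        with pytest.raises(InvalidInputError):
            PropagationConfig(n_layers=-1)

    def test_layer_weights_length_checked(self):
        with pytest.raises(InvalidInputError):
            PropagationConfig(n_layers=2, layer_weights=[np.eye(2)])


class TestNetworkIO:
    def test_edge_list_round_trip(self, tmp_path, chain_network):
        path = tmp_path / "net.tsv"
        write_edge_list(chain_network, path)
        back = read_edge_list(path, genes=chain_network.genes)
        assert np.array_equal(back.adjacency, chain_network.adjacency)

    def test_header_and_comments_skipped(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("# regulation edges\nsource_gene\ttarget_gene\na\tb\n")
        net = read_edge_list(path)
        assert net.genes == ["a", "b"]
        assert net.n_edges == 1

    def test_duplicate_edges_collapsed(self, tmp_path, caplog):
        path = tmp_path / "net.tsv"
        path.write_text("a\tb\na\tb\nb\ta\n")
        with caplog.at_level("WARNING"):
            net = read_edge_list(path)
        assert net.n_edges == 2
        assert any("duplicate" in r.message for r in caplog.records)

    def test_gene_cancer_round_trip(self, tmp_path):
        w = GeneCancerWeights(["a", "b"], ["BRCA", "LUAD"], np.array([[1.0, 0], [0, 1.0]]))
        path = tmp_path / "gc.tsv"
        write_gene_cancer(w, path)
        back = read_gene_cancer(path)
        assert back.genes == w.genes
        assert back.cancers == w.cancers
        assert np.array_equal(back.values, w.values)

    def test_gene_cancer_rejects_non_binary(self, tmp_path):
        path = tmp_path / "gc.tsv"
        path.write_text("gene\tBRCA\na\t0.5\n")
        with pytest.raises(InvalidInputError, match="0/1"):
            read_gene_cancer(path)
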