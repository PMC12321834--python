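import numpy as np
import pytest

from cmpnntox import cmpnn
from cmpnntox.cmpnn import (
    ConfigurationError,
    MessageState,
    ModelConfig,
    aggregate_messages,
    compute_booster,
    forward_reference,
    initialize_states,
    predict,
    readout,
    update_edge_states,
    update_node_states,
)
from cmpnntox.molgraph import MolecularGraph, batch_graphs, smiles_to_graph

from conftest import path_graph_1d, scalar_params


def star_graph(edge_states):
    """Edges all pointing into node 0, with prescribed edge states."""
    k = len(edge_states)
    graph = MolecularGraph(
        smiles="<synthetic star>",
        atom_feats=np.zeros((k + 1, 1)),
        edge_feats=np.zeros((k, 1)),
        edge_src=np.arange(1, k + 1),
        edge_dst=np.zeros(k, dtype=np.intp),
        rev_edge=np.arange(k),
    )
    state = MessageState(
        node_states=np.zeros((k + 1, len(edge_states[0]))),
        edge_states=np.array(edge_states, dtype=float),
    )
    return graph, state


class TestMessagePassingOps:
    def test_initialize_zero_weights_give_zero_states(self, fixture_graphs):
        g = fixture_graphs["ethanol"]
        params = {
            "W_atom_in": np.zeros((g.atom_feats.shape[1], 4)),
            "W_bond_in": np.zeros((g.atom_feats.shape[1] + g.edge_feats.shape[1], 4)),
        }
        state = initialize_states(g, params)
        assert not state.node_states.any() and not state.edge_states.any()
        assert state.node_states.shape == (3, 4)
        assert state.edge_states.shape == (4, 4)

    def test_initialize_single_atom_has_no_edge_states(self, fixture_graphs):
        g = fixture_graphs["methane"]
        params = {
            "W_atom_in": np.ones((g.atom_feats.shape[1], 2)),
            "W_bond_in": np.ones((g.atom_feats.shape[1] + g.edge_feats.shape[1], 2)),
        }
        state = initialize_states(g, params)
        assert state.node_states.shape == (1, 2)
        assert state.edge_states.shape == (0, 2)

    def test_initialize_width_mismatch_raises(self, fixture_graphs):
        g = fixture_graphs["ethanol"]
        params = {"W_atom_in": np.zeros((5, 4)), "W_bond_in": np.zeros((9, 4))}
        with pytest.raises(ConfigurationError):
            initialize_states(g, params)

    def test_aggregate_single_incoming_edge(self):
        graph, state = star_graph([[1.0, -2.0]])
        m = aggregate_messages(state, graph)
        assert np.array_equal(m[0], [1.0, -2.0])

    def test_aggregate_hand_sum(self):
        graph, state = star_graph([[1.0, 2.0], [3.0, 4.0]])
        m = aggregate_messages(state, graph)
        assert np.array_equal(m[0], [4.0, 6.0])

    def test_aggregate_isolated_nodes_get_zero(self):
        graph, state = star_graph([[1.0, 2.0]])
        m = aggregate_messages(state, graph)
        assert np.array_equal(m[1], [0.0, 0.0])

    def test_aggregate_invariant_to_edge_order(self):
        graph, state = star_graph([[1.0, 2.0], [3.0, 4.0], [5.0, 0.5]])
        m1 = aggregate_messages(state, graph)
        perm = [2, 0, 1]
        graph.edge_dst = graph.edge_dst[perm]
        state.edge_states = state.edge_states[perm]
        assert np.allclose(m1, aggregate_messages(state, graph))

    def test_booster_single_edge_is_that_edge(self):
        graph, state = star_graph([[1.0, 5.0]])
        assert np.array_equal(compute_booster(state, graph)[0], [1.0, 5.0])

    def test_booster_elementwise_max(self):
        graph, state = star_graph([[1.0, 5.0], [3.0, 2.0]])
        assert np.array_equal(compute_booster(state, graph)[0], [3.0, 5.0])

    def test_booster_isolated_node_zero(self):
        graph, state = star_graph([[1.0, 5.0]])
        assert np.array_equal(compute_booster(state, graph)[1], [0.0, 0.0])

    def test_node_update_zero_params_zero_output(self):
        graph, state = star_graph([[1.0, 2.0], [3.0, 4.0]])
        state.messages = aggregate_messages(state, graph)
        state.boosters = compute_booster(state, graph)
        out = update_node_states(state, {"W_node": np.zeros((6, 2))})
        assert not out.any() and out.shape == state.node_states.shape

    def test_edge_update_zero_matrix_is_identity(self):
        graph, state = star_graph([[1.0, 2.0], [3.0, 4.0]])
        new = update_edge_states(
            state, graph, {"W_comm": np.zeros((4, 2))}, np.ones((3, 2))
        )
        assert np.array_equal(new, state.edge_states)

    def test_edge_update_rectified_residual_never_decreases(self):
        rng = np.random.default_rng(0)
        graph, state = star_graph(rng.normal(size=(3, 4)).tolist())
        params = {"W_comm": rng.normal(size=(8, 4))}
        new = update_edge_states(state, graph, params, rng.normal(size=(4, 4)))
        assert np.all(new >= state.edge_states)


class TestScalarHandTrace:
    """Width-1 forward pass with all-ones weights, checked against arithmetic
    done by hand over the aggregate/boost/update equations."""

    def test_two_node_path_message_passing(self):
        graph = path_graph_1d(x0=2.0, x1=3.0, bond=1.0)
        params = scalar_params()
        state = initialize_states(graph, params)
        assert np.array_equal(state.node_states, [[2.0], [3.0]])
        assert np.array_equal(state.edge_states, [[3.0], [4.0]])  # relu(x_src + bond)
        state.messages = aggregate_messages(state, graph)
        state.boosters = compute_booster(state, graph)
        assert np.array_equal(state.messages, [[4.0], [3.0]])
        assert np.array_equal(state.boosters, [[4.0], [3.0]])
        new_nodes = update_node_states(state, params)
        # h = relu(h_prev + m*b + b): 2+16+4=22, 3+9+3=15
        assert np.array_equal(new_nodes, [[22.0], [15.0]])
        new_edges = update_edge_states(state, graph, params, new_nodes)
        # h_e + relu(h_dst + h_e): 3+relu(15+3)=21, 4+relu(22+4)=30
        assert np.array_equal(new_edges, [[21.0], [30.0]])

    def test_two_way_concat_variant(self):
        graph = path_graph_1d(x0=2.0, x1=3.0, bond=1.0)
        params = scalar_params(depth_in=2)
        state = initialize_states(graph, params)
        state.messages = aggregate_messages(state, graph)
        state.boosters = compute_booster(state, graph)
        new_nodes = update_node_states(state, params, booster_in_concat=False)
        assert np.array_equal(new_nodes, [[18.0], [12.0]])  # h + m*b only

    def test_predict_unit_weights_sigmoid_one(self):
        params = scalar_params()
        # head: sigma(relu(1*1+0)*1+0) = sigma(1)
        assert predict(np.array([1.0]), params) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12
        )


class TestPredictHead:
    def test_zero_head_gives_half(self):
        params = scalar_params()
        params["ffn_W0"] = np.zeros((1, 1))
        params["ffn_W1"] = np.zeros((1, 1))
        assert predict(np.array([3.7]), params) == 0.5

    def test_monotone_in_presigmoid_value(self):
        params = scalar_params()
        probs = [predict(np.array([v]), params) for v in (0.1, 0.5, 2.0)]
        assert probs == sorted(probs)
        assert all(0 < p < 1 for p in probs)


class TestReadout:
    def test_single_node_equals_one_cell_step(self):
        params = scalar_params()
        graph = MolecularGraph(
            smiles="<synthetic single node>",
            atom_feats=np.array([[1.5]]),
            edge_feats=np.zeros((0, 1)),
            edge_src=np.zeros(0, dtype=np.intp),
            edge_dst=np.zeros(0, dtype=np.intp),
            rev_edge=np.zeros(0, dtype=np.intp),
        )
        state = MessageState(
            node_states=np.array([[0.7]]), edge_states=np.zeros((0, 1))
        )
        out = readout(state, graph, params)
        expected = cmpnn._gru_cell_np(np.array([[0.7]]), np.zeros((1, 1)), params)
        assert np.allclose(out, expected[0])

    def test_fixed_width_regardless_of_molecule_size(self, small_params):
        mc, params = small_params(hidden=16)
        for smi in ("C", "CCCCCCCCCCCCCCCCCCCCCCCCC"):
            g = smiles_to_graph(smi)
            state = initialize_states(g, params)
            assert readout(state, g, params).shape == (16,)


class TestForwardEquivalence:
    def test_batched_forward_matches_loop_reference(self, fixture_graphs, small_params):
        mc, params = small_params(hidden=16, seed=1)
        graphs = list(fixture_graphs.values())
        logits = cmpnn.forward_batch(batch_graphs(graphs), params, mc).data[:, 0]
        batched = 1 / (1 + np.exp(-logits))
        for g, p in zip(graphs, batched):
            assert p == pytest.approx(forward_reference(g, params, mc), abs=1e-5)

    def test_batching_invariance(self, fixture_graphs, small_params):
        mc, params = small_params(hidden=16, seed=2)
        graphs = list(fixture_graphs.values())
        together = cmpnn.predict_proba(graphs, params, mc)
        alone = np.array([cmpnn.predict_proba([g], params, mc)[0] for g in graphs])
        assert np.allclose(together, alone, atol=1e-5)

    def test_two_way_concat_config_also_equivalent(self, fixture_graphs, small_params):
        mc, params = small_params(hidden=16, seed=3, booster_in_concat=False)
        graphs = list(fixture_graphs.values())
        logits = cmpnn.forward_batch(batch_graphs(graphs), params, mc).data[:, 0]
        batched = 1 / (1 + np.exp(-logits))
        for g, p in zip(graphs, batched):
            assert p == pytest.approx(forward_reference(g, params, mc), abs=1e-5)

    def test_probabilities_strictly_inside_unit_interval(self, fixture_graphs, small_params):
        mc, params = small_params(hidden=16, seed=4)
        probs = cmpnn.predict_proba(list(fixture_graphs.values()), params, mc)
        assert np.all((probs > 0) & (probs < 1))


class TestConfigValidation:
    def test_defaults_match_published_table(self):
        mc = ModelConfig()
        assert (mc.hidden_size, mc.depth, mc.bias) == (300, 3, False)
        assert (mc.ffn_num_layers, mc.ffn_width) == (2, 300)
        assert mc.atom_messages is False and mc.undirected is False

    @pytest.mark.parametrize(
        "kwargs",
        [{"hidden_size": 0}, {"depth": 0}, {"atom_messages": True}, {"undirected": True}],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ModelConfig(**kwargs)
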