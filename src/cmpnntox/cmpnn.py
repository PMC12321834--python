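"""Communicative message passing network for molecular toxicity prediction.

The model operates on directed molecular graphs. One round of message passing:

1. aggregate: each atom sums the embeddings of its incoming directed bonds,
   ``m_v = sum_{u->v} h_{u->v}``;
2. booster:   ``b_v = max_{u->v} h_{u->v}`` (element-wise), amplifying the
   most informative bond contributions; the boosted message is
   ``m'_v = m_v (*) b_v``;
3. node update: ``h_v = ReLU(W_node [h_v_prev || m'_v || b_v])`` (bias-free);
4. node-edge communication: each directed bond absorbs the fresh state of its
   target atom through a rectified residual,
   ``h_{u->v} <- h_{u->v} + ReLU(W_comm [h_v || h_{u->v}])``.

After ``depth`` rounds a gated recurrent unit is run over each molecule's atom
states in canonical order and the per-step outputs are summed into a
fixed-length molecular embedding; a two-layer feed-forward head with dropout
and a sigmoid produces the toxicity probability.

Two implementations share one parameter set: a vectorized batched forward on
the autodiff tape (used for training) and a plain nested-loop reference over
single graphs (used as the independent oracle in equivalence tests and to
expose each step individually).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .molgraph import GraphBatch, MolecularGraph, batch_graphs
from .nn import autodiff as ad
from .nn.autodiff import Tensor


class ConfigurationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults reproduce the published setup)."""

    hidden_size: int = 300
    depth: int = 3
    bias: bool = False
    activation: str = "relu"
    ffn_num_layers: int = 2
    ffn_hidden_size: int | None = None  # None -> hidden_size
    dropout: float = 0.0
    atom_messages: bool = False   # must stay False (edge-centred messages)
    undirected: bool = False      # must stay False (directed graph)
    booster_in_concat: bool = True  # include b_v alongside m'_v in node update

    def __post_init__(self):
        if self.hidden_size <= 0:
            raise ConfigurationError("hidden_size must be positive")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.atom_messages or self.undirected:
            raise ConfigurationError(
                "atom_messages/undirected modes are not part of this model"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")

    @property
    def ffn_width(self) -> int:
        return self.ffn_hidden_size or self.hidden_size

    @property
    def node_in_width(self) -> int:
        return (3 if self.booster_in_concat else 2) * self.hidden_size


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(
    config: ModelConfig, atom_fdim: int, bond_fdim: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """Glorot-initialized learnable weights for the given feature widths.

    Message-passing linear maps are bias-free; the GRU gates and the head
    retain their offsets.
    """
    h = config.hidden_size
    params: dict[str, np.ndarray] = {
        "W_atom_in": _glorot(rng, atom_fdim, h),
        "W_bond_in": _glorot(rng, atom_fdim + bond_fdim, h),
        "W_node": _glorot(rng, config.node_in_width, h),
        "W_comm": _glorot(rng, 2 * h, h),
    }
    for gate in ("z", "r", "n"):
        params[f"gru_Wx{gate}"] = _glorot(rng, h, h)
        params[f"gru_Wh{gate}"] = _glorot(rng, h, h)
        params[f"gru_bx{gate}"] = np.zeros(h)
        params[f"gru_bh{gate}"] = np.zeros(h)
    widths = [h] + [config.ffn_width] * (config.ffn_num_layers - 1) + [1]
    for i, (win, wout) in enumerate(zip(widths[:-1], widths[1:])):
        params[f"ffn_W{i}"] = _glorot(rng, win, wout)
        params[f"ffn_b{i}"] = np.zeros(wout)
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


def parameters_as_arrays(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: v.data.copy() for k, v in params.items()}


def arrays_as_parameters(arrays: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v.copy(), requires_grad=True) for k, v in arrays.items()}


# ---------------------------------------------------------------------------
# Reference implementation: plain loops over one graph, no batching, no tape.
# Exposes each message-passing step individually; serves as the oracle the
# vectorized forward is tested against.
# ---------------------------------------------------------------------------


@dataclass
class MessageState:
    """Intermediate state of message passing at iteration ``t``."""

    node_states: np.ndarray          # (n_atoms, hidden)
    edge_states: np.ndarray          # (n_edges, hidden)
    messages: np.ndarray | None = None        # m_v
    boosters: np.ndarray | None = None        # b_v
    boosted_messages: np.ndarray | None = None  # m'_v
    t: int = 0


def _np(params, key) -> np.ndarray:
    v = params[key]
    return v.data if isinstance(v, Tensor) else np.asarray(v)


def initialize_states(graph: MolecularGraph, params) -> MessageState:
    """Project raw atom/bond features into hidden width (rectified)."""
    W_a, W_b = _np(params, "W_atom_in"), _np(params, "W_bond_in")
    if graph.atom_feats.shape[1] != W_a.shape[0]:
        raise ConfigurationError(
            f"atom feature width {graph.atom_feats.shape[1]} does not match "
            f"input projection {W_a.shape[0]}"
        )
    h_v = np.maximum(graph.atom_feats @ W_a, 0.0)
    bond_in = np.concatenate(
        [graph.atom_feats[graph.edge_src], graph.edge_feats], axis=1
    )
    h_e = np.maximum(bond_in @ W_b, 0.0)
    return MessageState(node_states=h_v, edge_states=h_e, t=0)


def aggregate_messages(state: MessageState, graph: MolecularGraph) -> np.ndarray:
    """``m_v = sum`` of incoming edge states; zero vector if no incoming edges."""
    h = state.edge_states.shape[1] if state.edge_states.size else state.node_states.shape[1]
    m = np.zeros((graph.n_atoms, h))
    np.add.at(m, graph.edge_dst, state.edge_states)
    return m


def compute_booster(state: MessageState, graph: MolecularGraph) -> np.ndarray:
    """``b_v`` = element-wise max of incoming edge states; zero if none."""
    h = state.node_states.shape[1]
    b = np.full((graph.n_atoms, h), -np.inf)
    if graph.n_edges:
        np.maximum.at(b, graph.edge_dst, state.edge_states)
    b[~np.isfinite(b)] = 0.0
    return b


def update_node_states(state: MessageState, params, booster_in_concat=True) -> np.ndarray:
    """Bias-free rectified linear node update over the boosted message."""
    mp = state.messages * state.boosters
    pieces = [state.node_states, mp, state.boosters] if booster_in_concat else [
        state.node_states, mp,
    ]
    return np.maximum(np.concatenate(pieces, axis=1) @ _np(params, "W_node"), 0.0)


def update_edge_states(
    state: MessageState, graph: MolecularGraph, params, new_node_states: np.ndarray
) -> np.ndarray:
    """Rectified residual communication from target atoms into edges."""
    if graph.n_edges == 0:
        return state.edge_states.copy()
    comm_in = np.concatenate(
        [new_node_states[graph.edge_dst], state.edge_states], axis=1
    )
    return state.edge_states + np.maximum(comm_in @ _np(params, "W_comm"), 0.0)


def _gru_cell_np(x: np.ndarray, h: np.ndarray, params) -> np.ndarray:
    def gate(name):
        return (
            x @ _np(params, f"gru_Wx{name}") + _np(params, f"gru_bx{name}"),
            h @ _np(params, f"gru_Wh{name}") + _np(params, f"gru_bh{name}"),
        )

    xz, hz = gate("z")
    xr, hr = gate("r")
    xn, hn = gate("n")
    z = 1.0 / (1.0 + np.exp(-(xz + hz)))
    r = 1.0 / (1.0 + np.exp(-(xr + hr)))
    n = np.tanh(xn + r * hn)
    return (1.0 - z) * n + z * h


def readout(state: MessageState, graph: MolecularGraph, params) -> np.ndarray:
    """GRU over atom states in canonical order; outputs summed to one vector."""
    if graph.n_atoms == 0:
        raise DegenerateInputError("cannot read out a molecule with no atoms")
    width = state.node_states.shape[1]
    h = np.zeros((1, width))
    total = np.zeros(width)
    for v in range(graph.n_atoms):
        h = _gru_cell_np(state.node_states[v : v + 1], h, params)
        total += h[0]
    return total


def predict(embedding: np.ndarray, params, n_layers: int = 2) -> float:
    """Feed-forward head + sigmoid; dropout is inference-disabled."""
    x = np.atleast_2d(embedding)
    for i in range(n_layers):
        x = x @ _np(params, f"ffn_W{i}") + _np(params, f"ffn_b{i}")
        if i < n_layers - 1:
            x = np.maximum(x, 0.0)
    return float(1.0 / (1.0 + np.exp(-x[0, 0])))


def forward_reference(graph: MolecularGraph, params, config: ModelConfig) -> float:
    """Full forward pass via the per-step reference ops; returns probability."""
    state = initialize_states(graph, params)
    for t in range(1, config.depth + 1):
        state.messages = aggregate_messages(state, graph)
        state.boosters = compute_booster(state, graph)
        state.boosted_messages = state.messages * state.boosters
        new_nodes = update_node_states(state, params, config.booster_in_concat)
        if t < config.depth:
            state.edge_states = update_edge_states(state, graph, params, new_nodes)
        state.node_states = new_nodes
        state.t = t
    h_mol = readout(state, graph, params)
    return predict(h_mol, params, config.ffn_num_layers)


# ---------------------------------------------------------------------------
# Vectorized batched forward on the autodiff tape (training path).
# ---------------------------------------------------------------------------


def _gru_cell(x: Tensor, h: Tensor, params) -> Tensor:
    z = ad.sigmoid(
        ad.matmul(x, params["gru_Wxz"]) + params["gru_bxz"]
        + ad.matmul(h, params["gru_Whz"]) + params["gru_bhz"]
    )
    r = ad.sigmoid(
        ad.matmul(x, params["gru_Wxr"]) + params["gru_bxr"]
        + ad.matmul(h, params["gru_Whr"]) + params["gru_bhr"]
    )
    n = ad.tanh(
        ad.matmul(x, params["gru_Wxn"]) + params["gru_bxn"]
        + r * (ad.matmul(h, params["gru_Whn"]) + params["gru_bhn"])
    )
    return (1.0 - z) * n + z * h


def forward_batch(
    batch: GraphBatch,
    params: dict[str, Tensor],
    config: ModelConfig,
    dropout_rng: np.random.Generator | None = None,
) -> Tensor:
    """Batched forward pass; returns logits of shape (n_graphs, 1).

    Passing ``dropout_rng`` enables head dropout (training mode).
    """
    if (batch.atom_counts == 0).any():
        raise DegenerateInputError("batch contains a molecule with no atoms")
    n_atoms = batch.n_atoms
    f_atoms = Tensor(batch.atom_feats)
    f_bonds = Tensor(
        np.concatenate([batch.atom_feats[batch.edge_src], batch.edge_feats], axis=1)
    )
    h_v = ad.relu(ad.matmul(f_atoms, params["W_atom_in"]))
    h_e = ad.relu(ad.matmul(f_bonds, params["W_bond_in"]))

    for t in range(1, config.depth + 1):
        m = ad.segment_sum(h_e, batch.edge_dst, n_atoms)
        b = ad.segment_max(h_e, batch.edge_dst, n_atoms)
        pieces = [h_v, m * b, b] if config.booster_in_concat else [h_v, m * b]
        h_v = ad.relu(ad.matmul(ad.concat(pieces), params["W_node"]))
        if t < config.depth:
            comm_in = ad.concat([ad.gather_rows(h_v, batch.edge_dst), h_e])
            h_e = h_e + ad.relu(ad.matmul(comm_in, params["W_comm"]))

    # GRU readout, vectorized across molecules; the recurrence is confined to
    # each molecule via masking, so batching cannot leak state across graphs.
    n_graphs = batch.n_graphs
    counts = batch.atom_counts
    offsets = batch.atom_offsets
    width = config.hidden_size
    h = Tensor(np.zeros((n_graphs, width)))
    h_mol = Tensor(np.zeros((n_graphs, width)))
    for t in range(int(counts.max())):
        active = counts > t
        idx = offsets + np.minimum(t, counts - 1)  # dummy row when inactive
        mask = Tensor(active.astype(np.float64)[:, None])
        x_t = ad.gather_rows(h_v, idx)
        h_new = _gru_cell(x_t, h, params)
        h = mask * h_new + (1.0 - mask) * h
        h_mol = h_mol + mask * h_new

    x = h_mol
    for i in range(config.ffn_num_layers):
        if dropout_rng is not None and config.dropout > 0.0:
            keep = (dropout_rng.random(x.shape) >= config.dropout).astype(np.float64)
            x = x * Tensor(keep / (1.0 - config.dropout))
        x = ad.matmul(x, params[f"ffn_W{i}"]) + params[f"ffn_b{i}"]
        if i < config.ffn_num_layers - 1:
            x = ad.relu(x)
    return x


def predict_proba(
    graphs, params: dict[str, Tensor], config: ModelConfig, batch_size: int = 50
) -> np.ndarray:
    """Toxicity probabilities for a sequence of graphs (inference mode)."""
    graphs = list(graphs)
    out = np.empty(len(graphs))
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start : start + batch_size]
        logits = forward_batch(batch_graphs(chunk), params, config).data[:, 0]
        out[start : start + len(chunk)] = 1.0 / (1.0 + np.exp(-logits))
    return out
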