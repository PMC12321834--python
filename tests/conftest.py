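import numpy as np
import pytest

from cmpnntox import cmpnn, synthetic
from cmpnntox.molgraph import MolecularGraph, smiles_to_graph
from cmpnntox.nn.autodiff import Tensor


@pytest.fixture(scope="session")
def fixture_molecules():
    return synthetic.fixtures()


@pytest.fixture(scope="session")
def fixture_graphs(fixture_molecules):
    return {name: smiles_to_graph(smi) for name, (smi, _, _) in fixture_molecules.items()}


@pytest.fixture
def tiny_dataset_csv(tmp_path):
    """Factory for small compound CSVs."""

    def make(rows, name="data.csv", header="smiles,label"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(f"{s},{l}" for s, l in rows) + "\n")
        return path

    return make


def scalar_params(depth_in=3):
    """All-ones 1-dimensional weights for hand-traceable forward passes."""
    p = {
        "W_atom_in": np.ones((1, 1)),
        "W_bond_in": np.ones((2, 1)),
        "W_node": np.ones((depth_in, 1)),
        "W_comm": np.ones((2, 1)),
        "ffn_W0": np.ones((1, 1)),
        "ffn_b0": np.zeros(1),
        "ffn_W1": np.ones((1, 1)),
        "ffn_b1": np.zeros(1),
    }
    for gate in ("z", "r", "n"):
        p[f"gru_Wx{gate}"] = np.ones((1, 1))
        p[f"gru_Wh{gate}"] = np.ones((1, 1))
        p[f"gru_bx{gate}"] = np.zeros(1)
        p[f"gru_bh{gate}"] = np.zeros(1)
    return p


def path_graph_1d(x0=2.0, x1=3.0, bond=1.0):
    """Two atoms joined by one bond, scalar features — for hand traces."""
    return MolecularGraph(
        smiles="<synthetic 2-node path>",
        atom_feats=np.array([[x0], [x1]]),
        edge_feats=np.array([[bond], [bond]]),
        edge_src=np.array([0, 1]),
        edge_dst=np.array([1, 0]),
        rev_edge=np.array([1, 0]),
    )


@pytest.fixture
def small_params():
    """Seeded small-width parameters matched to real molecule features."""

    def make(hidden=16, seed=0, booster_in_concat=True):
        mc = cmpnn.ModelConfig(hidden_size=hidden, booster_in_concat=booster_in_concat)
        g = smiles_to_graph("CCO")
        rng = np.random.default_rng(seed)
        params = cmpnn.init_parameters(
            mc, g.atom_feats.shape[1], g.edge_feats.shape[1], rng
        )
        return mc, params

    return make
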