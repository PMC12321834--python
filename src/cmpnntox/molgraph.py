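"""Molecular graphs with atom/bond feature vectors for message passing.

A molecule is a directed graph: every chemical bond contributes two directed
edges (u->v and v->u) carrying identical bond features, and each directed edge
knows the index of its reverse. Atoms are renumbered into canonical order at
construction so that downstream order-sensitive operations (the recurrent
readout) are invariant to how the SMILES string was spelled.

Featurization follows the de-facto standard of directed message passing
networks: element one-hot (+"other"), degree, formal charge, chirality tag,
attached-hydrogen count, hybridization, aromaticity flag, and atomic mass
scaled by 1/100; bonds carry order class, conjugation, ring membership and
stereo class. Hydrogens are implicit (counted, not graph nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

DEFAULT_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se")

_DEGREES = (0, 1, 2, 3, 4, 5)
_FORMAL_CHARGES = (-2, -1, 0, 1, 2)
_CHIRAL_TAGS = tuple(range(4))
_NUM_HS = (0, 1, 2, 3, 4)
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_N_STEREO = 6


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


class EmptyBatchError(ValueError):
    """Raised when batching an empty collection of graphs."""


def _one_hot(value, choices) -> list[float]:
    """One-hot over ``choices`` with a trailing 'other' slot."""
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[list(choices).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_feature_length(elements=DEFAULT_ELEMENTS) -> int:
    return (
        len(elements) + 1
        + len(_DEGREES) + 1
        + len(_FORMAL_CHARGES) + 1
        + len(_CHIRAL_TAGS) + 1
        + len(_NUM_HS) + 1
        + len(_HYBRIDIZATIONS) + 1
        + 1  # aromatic
        + 1  # mass / 100
    )


def bond_feature_length() -> int:
    return len(_BOND_TYPES) + 1 + 1 + 1 + _N_STEREO + 1


def atom_features(atom: Chem.Atom, elements=DEFAULT_ELEMENTS) -> np.ndarray:
    feats = (
        _one_hot(atom.GetSymbol(), elements)
        + _one_hot(atom.GetTotalDegree(), _DEGREES)
        + _one_hot(atom.GetFormalCharge(), _FORMAL_CHARGES)
        + _one_hot(int(atom.GetChiralTag()), _CHIRAL_TAGS)
        + _one_hot(atom.GetTotalNumHs(), _NUM_HS)
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() / 100.0]
    )
    return np.asarray(feats, dtype=np.float64)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    feats = (
        _one_hot(bond.GetBondType(), _BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
        + _one_hot(int(bond.GetStereo()), tuple(range(_N_STEREO)))
    )
    return np.asarray(feats, dtype=np.float64)


@dataclass
class MolecularGraph:
    """Directed molecular graph with per-atom and per-directed-edge features.

    ``edge_src``/``edge_dst`` index into the atom array; ``rev_edge`` maps each
    directed edge to its reverse and is an involution.
    """

    smiles: str
    atom_feats: np.ndarray  # (n_atoms, atom_fdim)
    edge_feats: np.ndarray  # (n_edges, bond_fdim)
    edge_src: np.ndarray    # (n_edges,)
    edge_dst: np.ndarray    # (n_edges,)
    rev_edge: np.ndarray    # (n_edges,)

    @property
    def n_atoms(self) -> int:
        return self.atom_feats.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]

    def incoming_edges(self, v: int) -> np.ndarray:
        """Indices of directed edges u->v."""
        return np.flatnonzero(self.edge_dst == v)


def smiles_to_graph(smiles: str, elements=DEFAULT_ELEMENTS) -> MolecularGraph:
    """Build the directed graph for one molecule, atoms in canonical order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    ranks = list(Chem.CanonicalRankAtoms(mol))
    order = sorted(range(mol.GetNumAtoms()), key=ranks.__getitem__)
    mol = Chem.RenumberAtoms(mol, order)

    n = mol.GetNumAtoms()
    af = np.zeros((n, atom_feature_length(elements)))
    for atom in mol.GetAtoms():
        af[atom.GetIdx()] = atom_features(atom, elements)

    # bonds sorted and oriented by canonical atom index, so the whole graph
    # (not just the atom array) is invariant to the SMILES spelling
    bonds = sorted(
        mol.GetBonds(),
        key=lambda b: tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))),
    )
    src, dst, ef, rev = [], [], [], []
    for bond in bonds:
        u, v = sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bf = bond_features(bond)
        e = len(src)
        src += [u, v]
        dst += [v, u]
        ef += [bf, bf]
        rev += [e + 1, e]
    edge_feats = (
        np.asarray(ef) if ef else np.zeros((0, bond_feature_length()))
    )
    return MolecularGraph(
        smiles=smiles,
        atom_feats=af,
        edge_feats=edge_feats,
        edge_src=np.asarray(src, dtype=np.intp),
        edge_dst=np.asarray(dst, dtype=np.intp),
        rev_edge=np.asarray(rev, dtype=np.intp),
    )


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with per-node membership."""

    atom_feats: np.ndarray
    edge_feats: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    rev_edge: np.ndarray
    node_graph: np.ndarray        # graph membership per node
    atom_offsets: np.ndarray      # start node index per member graph
    atom_counts: np.ndarray       # nodes per member graph
    members: list = field(default_factory=list, repr=False)

    @property
    def n_graphs(self) -> int:
        return len(self.atom_counts)

    @property
    def n_atoms(self) -> int:
        return self.atom_feats.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]

    def unbatch(self) -> list[MolecularGraph]:
        return list(self.members)


def batch_graphs(graphs) -> GraphBatch:
    """Concatenate graphs into one disjoint union; indices offset per member."""
    graphs = list(graphs)
    if not graphs:
        raise EmptyBatchError("cannot batch zero graphs")
    counts = np.array([g.n_atoms for g in graphs], dtype=np.intp)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    edge_offsets = np.concatenate(
        [[0], np.cumsum([g.n_edges for g in graphs])[:-1]]
    )
    return GraphBatch(
        atom_feats=np.concatenate([g.atom_feats for g in graphs]),
        edge_feats=np.concatenate([g.edge_feats for g in graphs]),
        edge_src=np.concatenate(
            [g.edge_src + off for g, off in zip(graphs, offsets)]
        ).astype(np.intp),
        edge_dst=np.concatenate(
            [g.edge_dst + off for g, off in zip(graphs, offsets)]
        ).astype(np.intp),
        rev_edge=np.concatenate(
            [g.rev_edge + eo for g, eo in zip(graphs, edge_offsets)]
        ).astype(np.intp),
        node_graph=np.repeat(np.arange(len(graphs)), counts),
        atom_offsets=offsets.astype(np.intp),
        atom_counts=counts,
        members=graphs,
    )
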