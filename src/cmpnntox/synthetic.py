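"""Synthetic compound datasets with a planted structure-toxicity rule.

Molecules are assembled by concatenating valence-safe SMILES fragments: a
chain of neutral extender fragments is closed by a terminal fragment, which
either carries a toxicophore (nitroaromatic or phthalate-diester pattern) or
is inert. A molecule containing any toxicophore substructure gets true label
1; each label then flips independently with probability ``noise`` to emulate
annotation error. Class balance is steered by drawing each molecule's class
from a Bernoulli(toxic_fraction) before assembly.

The planted patterns are chemically evocative of known reproductive-toxicant
families but are chosen purely for testability; no toxicological realism is
claimed beyond dataset size, balance and organic-molecule character.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .chem_io import CompoundRecord

# Single-attachment fragments written so plain string concatenation stays a
# valid SMILES chain (each begins at an atom and never reuses ring indices
# already open in the chain prefix).
NEUTRAL_EXTENDERS = (
    "C",
    "CC",
    "C(C)",
    "CO",
    "CC(C)",
    "c1ccc(cc1)",
    "C(=O)N",
    "CS",
    "C=C",
    "OC",
)
NEUTRAL_TERMINATORS = (
    "C",
    "CO",
    "C(C)C",
    "c1ccccc1",
    "C(=O)NC",
    "C#N",
    "CCl",
    "C(F)(F)F",
)
TOXIC_TERMINATORS = (
    "c1ccc(cc1)[N+](=O)[O-]",            # nitroaromatic
    "OC(=O)c1ccccc1C(=O)OCC",            # phthalate diester
    "COC(=O)c1ccccc1C(=O)OC",            # phthalate diester (methyl)
    "Cc1ccc(cc1[N+](=O)[O-])",           # nitrotoluene-like (extender position)
)

TOXICOPHORE_SMARTS = (
    "[c][N+](=O)[O-]",                                    # aromatic nitro
    "c1ccc(C(=O)O[C,c])c(C(=O)O[C,c])c1",                 # phthalate diester
)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 500
    toxic_fraction: float = 0.5
    noise: float = 0.05            # label flip rate epsilon
    max_extenders: int = 4
    seed: int = 0
    toxicophores: tuple[str, ...] = TOXICOPHORE_SMARTS

    def __post_init__(self):
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.n < 10:
            raise ValueError("n must be at least 10")


@dataclass
class GroundTruth:
    """Sidecar describing the planted rule of a generated dataset."""

    toxicophores: tuple[str, ...]
    noise: float
    seed: int
    true_labels: list[int] = field(default_factory=list)


def _patterns(smarts_list):
    pats = [Chem.MolFromSmarts(s) for s in smarts_list]
    if any(p is None for p in pats):
        raise GenerationError("invalid toxicophore SMARTS")
    return pats


def matches_toxicophore(smiles: str, smarts_list=TOXICOPHORE_SMARTS) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(mol.HasSubstructMatch(p) for p in _patterns(smarts_list))


def generate(config: GeneratorConfig) -> tuple[list[CompoundRecord], GroundTruth]:
    """Generate records plus the ground-truth rule; deterministic under seed."""
    import numpy as np

    rng = np.random.default_rng(config.seed)
    patterns = _patterns(config.toxicophores)
    records: list[CompoundRecord] = []
    truth = GroundTruth(
        toxicophores=config.toxicophores, noise=config.noise, seed=config.seed
    )
    attempts = 0
    while len(records) < config.n:
        attempts += 1
        if attempts > 50 * config.n:
            raise GenerationError("fragment grammar failed to reach target balance")
        want_toxic = rng.random() < config.toxic_fraction
        k = rng.integers(1, config.max_extenders + 1)
        chain = "".join(rng.choice(NEUTRAL_EXTENDERS, size=k))
        if want_toxic:
            chain += str(rng.choice(TOXIC_TERMINATORS))
        else:
            chain += str(rng.choice(NEUTRAL_TERMINATORS))
        mol = Chem.MolFromSmiles(chain)
        if mol is None:
            continue
        has_tox = any(mol.HasSubstructMatch(p) for p in patterns)
        if has_tox != want_toxic:
            continue  # neutral draw accidentally matched (or vice versa)
        true_label = int(has_tox)
        label = true_label ^ int(rng.random() < config.noise)
        records.append(
            CompoundRecord(
                identifier=f"syn{len(records):05d}",
                smiles=Chem.MolToSmiles(mol),
                label=label,
            )
        )
        truth.true_labels.append(true_label)
    return records, truth


def substructure_classifier_scores(records, smarts_list=TOXICOPHORE_SMARTS):
    """Oracle classifier: score 1 if any toxicophore matches, else 0.

    With zero label noise this classifier attains AUC 1.0 on generated data,
    establishing the learnability ceiling for trained models.
    """
    return [1.0 if matches_toxicophore(r.smiles, smarts_list) else 0.0 for r in records]


FIXTURE_MOLECULES = {
    # name: (smiles, expected n_atoms, expected n_directed_edges)
    "methane": ("C", 1, 0),
    "water": ("O", 1, 0),
    "ethanol": ("CCO", 3, 4),
    "benzene": ("c1ccccc1", 6, 12),
    "dimethyl_phthalate": ("COC(=O)c1ccccc1C(=O)OC", 14, 28),
}


def fixtures() -> dict[str, tuple[str, int, int]]:
    """Tiny named molecules with precomputed graph sizes for unit tests."""
    return dict(FIXTURE_MOLECULES)
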