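"""Compound-table I/O, Morgan fingerprints and physicochemical descriptors.

The input format is a delimited text table with a header, one row per
compound, holding a SMILES column and (for training data) a binary toxicity
label column (1 = reproductively toxic, 0 = non-toxic). Rows whose SMILES do
not parse are dropped with a logged warning so that large screens degrade
gracefully; the load result carries the kept/dropped tallies.

Fingerprints are binary Morgan/ECFP4 vectors (radius 2, 2048 bits).
Descriptors are the six used throughout small-molecule QSAR work: molecular
weight (Da), TPSA (A^2), Crippen logP, Lipinski H-bond donors/acceptors and
rotatable-bond count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator
from rdkit import RDLogger

from .molgraph import InvalidSmilesError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")

FP_RADIUS = 2
FP_NBITS = 2048

DESCRIPTOR_NAMES = ("weight", "tpsa", "logp", "hbd", "hba", "rot_bonds")


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class EmptyDatasetError(ValueError):
    """No valid rows survived loading."""


class DegenerateClassError(ValueError):
    """A per-class summary was requested for a class with no members."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: an identifier, its SMILES, and an optional binary label."""

    identifier: str
    smiles: str
    label: int | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class LoadResult:
    """Records kept from a compound table plus bookkeeping tallies."""

    records: list[CompoundRecord]
    n_kept: int
    n_dropped: int

    def class_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for r in self.records:
            if r.label is not None:
                counts[r.label] += 1
        return counts


def _parse(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def load_dataset(
    path,
    smiles_column: str = "smiles",
    label_column: str | None = "label",
    id_column: str | None = None,
    largest_fragment: bool = False,
) -> LoadResult:
    """Read a compound CSV, dropping (and counting) unparseable SMILES.

    ``label_column=None`` loads in prediction mode (labels absent). With
    ``largest_fragment=True`` salt/mixture SMILES are reduced to their largest
    covalent fragment; by default SMILES are taken as-is.
    """
    try:
        table = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"dataset not found: {path}") from exc
    if smiles_column not in table.columns:
        raise SchemaError(f"missing SMILES column {smiles_column!r}")
    if label_column is not None and label_column not in table.columns:
        raise SchemaError(f"missing label column {label_column!r}")

    records: list[CompoundRecord] = []
    n_dropped = 0
    for i, row in table.iterrows():
        smiles = str(row[smiles_column])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            n_dropped += 1
            logger.warning("dropping row %d: unparseable SMILES %r", i, smiles)
            continue
        if largest_fragment and "." in smiles:
            frags = sorted(smiles.split("."), key=len)
            smiles = frags[-1]
        label = None
        if label_column is not None:
            label = int(row[label_column])
        ident = str(row[id_column]) if id_column else str(i)
        records.append(CompoundRecord(identifier=ident, smiles=smiles, label=label))

    if not records:
        raise EmptyDatasetError(f"no valid SMILES rows in {path}")
    logger.info("loaded %d records (%d dropped)", len(records), n_dropped)
    return LoadResult(records=records, n_kept=len(records), n_dropped=n_dropped)


def write_dataset(records, path, smiles_column="smiles", label_column="label") -> None:
    """Write records back to CSV in order (inverse of :func:`load_dataset`)."""
    rows = {
        "identifier": [r.identifier for r in records],
        smiles_column: [r.smiles for r in records],
    }
    labels = [r.label for r in records]
    if any(l is not None for l in labels):
        rows[label_column] = labels
    pd.DataFrame(rows).to_csv(path, index=False)


_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_NBITS
)


def compute_fingerprint(record: CompoundRecord) -> np.ndarray:
    """Binary Morgan (ECFP4) fingerprint: radius 2, 2048 bits, {0,1} entries."""
    mol = _parse(record.smiles)
    fp = _fp_generator.GetFingerprint(mol)
    arr = np.zeros(FP_NBITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(records) -> np.ndarray:
    return np.stack([compute_fingerprint(r) for r in records])


@dataclass(frozen=True)
class DescriptorProfile:
    """Six physicochemical descriptors of one molecule."""

    weight: float   # molecular weight, Da
    tpsa: float     # topological polar surface area, A^2
    logp: float     # Crippen octanol-water logP
    hbd: int        # Lipinski H-bond donors
    hba: int        # Lipinski H-bond acceptors
    rot_bonds: int  # rotatable bonds

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}


def compute_descriptors(record: CompoundRecord) -> DescriptorProfile:
    mol = _parse(record.smiles)
    return DescriptorProfile(
        weight=Descriptors.MolWt(mol),
        tpsa=Descriptors.TPSA(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rot_bonds=Lipinski.NumRotatableBonds(mol),
    )


def descriptor_table(records) -> pd.DataFrame:
    """One row per compound with identifier, label and the six descriptors."""
    rows = []
    for r in records:
        d = compute_descriptors(r).as_dict()
        d["identifier"] = r.identifier
        d["label"] = r.label
        rows.append(d)
    return pd.DataFrame(rows, columns=["identifier", "label", *DESCRIPTOR_NAMES])


def summarize_descriptors(records) -> pd.DataFrame:
    """Median and quartiles of each descriptor, per toxicity class.

    Every record must carry a label; a class with zero members raises
    :class:`DegenerateClassError`. The median convention is the midpoint of
    the two central order statistics for even n.
    """
    table = descriptor_table(records)
    if table["label"].isna().any():
        raise ValueError("all records must carry a label for summarization")
    rows = []
    for cls in (0, 1):
        sub = table[table["label"] == cls]
        if sub.empty:
            raise DegenerateClassError(f"class {cls} has no members")
        for name in DESCRIPTOR_NAMES:
            vals = sub[name].to_numpy(dtype=float)
            rows.append(
                {
                    "class": cls,
                    "descriptor": name,
                    "q1": float(np.percentile(vals, 25)),
                    "median": float(np.median(vals)),
                    "q3": float(np.percentile(vals, 75)),
                }
            )
    return pd.DataFrame(rows)
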