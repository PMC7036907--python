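"""SMILES parsing, atom featurization, circular fingerprints and label assembly.

Molecules are handled as heavy-atom graphs (hydrogens implicit; attached-H
counts live inside the per-atom feature vector).  Atom order is the RDKit
canonical order for the canonical SMILES, which makes graph construction
deterministic for a given input structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "SmilesParseError",
    "AtomFeatureSpec",
    "MolGraph",
    "LabelMatrix",
    "MAX_DEGREE",
    "smiles_to_graph",
    "atom_feature_vector",
    "circular_fingerprint",
    "assemble_compound_labels",
    "read_compound_table",
    "read_smiles_file",
    "write_fingerprint_matrix",
]

#: Degrees above this value are clipped wherever a degree indexes a parameter
#: or a one-hot slot; organic valence essentially never exceeds it.
MAX_DEGREE = 6


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a non-empty molecule."""

    def __init__(self, smiles: str, reason: str = "not parseable"):
        self.smiles = smiles
        super().__init__(f"invalid SMILES {smiles!r}: {reason}")


@dataclass(frozen=True)
class AtomFeatureSpec:
    """Per-atom input encoding.

    The network learns its own high-level atom descriptions, but an initial
    fixed-length encoding is still needed.  The default is the conventional
    neural-fingerprint choice: one-hot element identity over a fixed list
    (unknown elements map to ``other``), one-hot topological degree 0-6,
    one-hot attached-hydrogen count 0-4, an aromaticity flag, and one-hot
    formal charge clipped to [-2, +2].
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "P", "Cl", "Br", "I")
    max_degree: int = MAX_DEGREE
    max_h: int = 4
    charge_range: tuple[int, int] = (-2, 2)

    @property
    def feature_dim(self) -> int:
        n_charge = self.charge_range[1] - self.charge_range[0] + 1
        return (len(self.elements) + 1) + (self.max_degree + 1) + (self.max_h + 1) + 1 + n_charge


@dataclass
class MolGraph:
    """Heavy-atom molecular graph.

    Attributes
    ----------
    atom_features : (num_atoms, feature_dim) float array
    neighbors : list of int lists, one per atom
    degrees : (num_atoms,) int array, ``degrees[v] == len(neighbors[v])``
    smiles : canonical SMILES the graph was built from
    """

    atom_features: np.ndarray
    neighbors: list[list[int]]
    degrees: np.ndarray
    smiles: str

    @property
    def num_atoms(self) -> int:
        return len(self.neighbors)

    @property
    def feature_dim(self) -> int:
        return self.atom_features.shape[1]


@dataclass
class LabelMatrix:
    """Compounds x tasks binary supervision matrix."""

    compound_ids: list[str]
    task_names: list[str]
    labels: np.ndarray  # (num_compounds, num_tasks) of {0, 1}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D matrix")
        if self.labels.shape != (len(self.compound_ids), len(self.task_names)):
            raise ValueError(
                f"label matrix shape {self.labels.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.task_names)} tasks"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("label entries must be 0 or 1")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("compound ids must be unique")

    @property
    def n_compounds(self) -> int:
        return self.labels.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def positive_counts(self) -> np.ndarray:
        return self.labels.sum(axis=0)


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def atom_feature_vector(atom: Chem.Atom, spec: AtomFeatureSpec | None = None) -> np.ndarray:
    """Encode a single RDKit atom as a fixed-length numeric vector."""
    spec = spec or AtomFeatureSpec()
    sym = atom.GetSymbol()
    try:
        elem_idx = spec.elements.index(sym)
    except ValueError:
        elem_idx = len(spec.elements)  # "other"
    deg = min(atom.GetDegree(), spec.max_degree)
    n_h = min(atom.GetTotalNumHs(), spec.max_h)
    lo, hi = spec.charge_range
    charge = int(np.clip(atom.GetFormalCharge(), lo, hi)) - lo
    return np.concatenate(
        [
            _one_hot(elem_idx, len(spec.elements) + 1),
            _one_hot(deg, spec.max_degree + 1),
            _one_hot(n_h, spec.max_h + 1),
            np.array([1.0 if atom.GetIsAromatic() else 0.0]),
            _one_hot(charge, hi - lo + 1),
        ]
    )


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles, "zero heavy atoms")
    return mol


def smiles_to_graph(smiles: str, feature_spec: AtomFeatureSpec | None = None) -> MolGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolGraph`.

    The molecule is canonicalized first so atom order is deterministic per
    structure.  Disconnected multi-fragment SMILES (e.g. salts) are kept as a
    single graph with several components; graph-level aggregation later sums
    over all atoms regardless of connectivity.
    """
    spec = feature_spec or AtomFeatureSpec()
    mol = _mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    mol = _mol_from_smiles(canonical)  # rebuild in canonical atom order

    n = mol.GetNumAtoms()
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        neighbors[i].append(j)
        neighbors[j].append(i)
    features = np.stack([atom_feature_vector(a, spec) for a in mol.GetAtoms()])
    degrees = np.array([len(nb) for nb in neighbors], dtype=np.int64)
    return MolGraph(atom_features=features, neighbors=neighbors, degrees=degrees, smiles=canonical)


def circular_fingerprint(smiles: str, radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Hashed circular (ECFP-style) fingerprint folded to ``n_bits`` bits.

    ``radius=2, n_bits=1024`` is the classical ECFP4/1024 setting.  Returns a
    binary uint8 vector; deterministic per input structure.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def assemble_compound_labels(
    herb_labels: pd.DataFrame,
    herb_compounds: pd.DataFrame,
) -> tuple[LabelMatrix, dict[str, str]]:
    """Build the compound x task label matrix from herb-level annotations.

    Each compound inherits the task labels of every herb it occurs in; a
    compound shared by several herbs receives the element-wise OR (union) of
    those herbs' label vectors.  Herbs with no label row are skipped.

    Parameters
    ----------
    herb_labels : DataFrame with column ``herb_id`` plus one 0/1 column per task.
    herb_compounds : DataFrame with columns ``herb_id, compound_id, smiles``.

    Returns
    -------
    (LabelMatrix, smiles_map) where ``smiles_map`` maps compound id to the
    canonical SMILES under which compounds were deduplicated.
    """
    task_names = [c for c in herb_labels.columns if c != "herb_id"]
    if not task_names:
        raise ValueError("herb_labels has no task columns")
    label_by_herb = {
        row["herb_id"]: np.asarray([int(row[t]) for t in task_names], dtype=np.int8)
        for _, row in herb_labels.iterrows()
    }

    # canonicalize before dedup so the same structure from two herbs merges
    rows: dict[str, np.ndarray] = {}
    smiles_map: dict[str, str] = {}
    for _, row in herb_compounds.iterrows():
        herb = row["herb_id"]
        if herb not in label_by_herb:
            continue  # herb with missing labels contributes nothing
        cid = str(row["compound_id"])
        canonical = Chem.MolToSmiles(_mol_from_smiles(row["smiles"]))
        if cid in rows:
            if smiles_map[cid] != canonical:
                warnings.warn(f"compound id {cid!r} maps to two different structures")
            rows[cid] |= label_by_herb[herb]
        else:
            rows[cid] = label_by_herb[herb].copy()
            smiles_map[cid] = canonical
    if not rows:
        raise ValueError("no labeled compounds: herb tables have empty intersection")

    compound_ids = list(rows)
    labels = np.stack([rows[c] for c in compound_ids])
    return LabelMatrix(compound_ids, task_names, labels), smiles_map


def read_compound_table(path) -> tuple[LabelMatrix, list[str]]:
    """Read a delimited compound table: ``compound_id, smiles, <task>...``.

    Returns the label matrix and the SMILES list aligned with its rows.
    """
    df = pd.read_csv(path)
    required = {"compound_id", "smiles"}
    if not required.issubset(df.columns):
        raise ValueError(f"compound table must have columns {sorted(required)}")
    task_names = [c for c in df.columns if c not in required]
    labels = df[task_names].to_numpy()
    lm = LabelMatrix([str(c) for c in df["compound_id"]], task_names, labels)
    return lm, list(df["smiles"])


def read_smiles_file(path) -> tuple[list[str], list[str]]:
    """Read a .smi file: one SMILES per line, optional id after whitespace."""
    smiles, ids = [], []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles.append(parts[0])
            ids.append(parts[1].strip() if len(parts) > 1 else f"mol{i}")
    return smiles, ids


def write_fingerprint_matrix(path, smiles_list: list[str], ids: list[str],
                             radius: int = 2, n_bits: int = 1024) -> None:
    """Export the dense 0/1 fingerprint matrix as delimited text."""
    mat = np.stack([circular_fingerprint(s, radius, n_bits) for s in smiles_list])
    df = pd.DataFrame(mat, columns=[f"bit{i}" for i in range(n_bits)])
    df.insert(0, "compound_id", ids)
    df.to_csv(path, index=False)
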