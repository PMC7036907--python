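"""Train/validation/test splitting: index, random, random-stratified, scaffold.

All strategies target 80/10/10 fractions.  The stratified strategy is an
iterative multi-label scheme (rarest task first) that guarantees every task
with at least 3 positives keeps at least one positive in each fold, which is
what makes heavily imbalanced tasks evaluable at all.  The scaffold strategy
keeps every Bemis-Murcko scaffold group intact within one fold, preventing
structural leakage between training and evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import LabelMatrix, SmilesParseError

__all__ = [
    "FRACTIONS",
    "SplitResult",
    "index_split",
    "random_split",
    "stratified_split",
    "scaffold_split",
    "bemis_murcko_scaffold",
]

FRACTIONS = (0.8, 0.1, 0.1)


@dataclass
class SplitResult:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    strategy: str
    seed: int | None = None
    fractions: tuple[float, float, float] = FRACTIONS

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.int64)
        self.valid = np.asarray(self.valid, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.train) + len(self.valid) + len(self.test)

    def validate(self) -> None:
        """Check disjointness and completeness over 0..n-1."""
        all_idx = np.concatenate([self.train, self.valid, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("folds overlap")
        if not np.array_equal(np.sort(all_idx), np.arange(self.n)):
            raise ValueError("folds do not cover all indices")


def _target_sizes(n: int) -> tuple[int, int, int]:
    # largest-remainder apportionment keeps every fold within one sample of
    # its nominal fraction for any n (ties broken in train/valid/test order)
    exact = np.asarray(FRACTIONS) * n
    sizes = np.floor(exact).astype(int)
    remainders = exact - sizes
    for f in np.argsort(-remainders, kind="stable")[: n - sizes.sum()]:
        sizes[f] += 1
    return int(sizes[0]), int(sizes[1]), int(sizes[2])


def index_split(n: int) -> SplitResult:
    """First 80% of samples (input order) -> train, next 10% -> valid, rest -> test."""
    if n < 10:
        raise ValueError(f"need n >= 10 samples to split, got {n}")
    n_train, n_valid, _ = _target_sizes(n)
    idx = np.arange(n)
    return SplitResult(idx[:n_train], idx[n_train:n_train + n_valid],
                       idx[n_train + n_valid:], strategy="index")


def random_split(n: int, seed: int = 0) -> SplitResult:
    """Seeded random permutation followed by an 80/10/10 cut."""
    if n < 10:
        raise ValueError(f"need n >= 10 samples to split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train, n_valid, _ = _target_sizes(n)
    return SplitResult(perm[:n_train], perm[n_train:n_train + n_valid],
                       perm[n_train + n_valid:], strategy="random", seed=seed)


def stratified_split(labels: LabelMatrix, seed: int = 0) -> SplitResult:
    """Iterative multi-label stratification, rarest task first.

    Tasks are processed in order of ascending positive count.  For each task
    its not-yet-assigned positives are distributed 80/10/10 at random, then
    bumped so that any task with >= 3 positives overall ends with >= 1
    positive in every fold (capacity permitting).  Remaining samples fill the
    folds at random to the target sizes.
    """
    n = labels.n_compounds
    if n < 10:
        raise ValueError(f"need n >= 10 samples to split, got {n}")
    y = labels.labels
    pos_counts = y.sum(axis=0)
    if pos_counts.max(initial=0) < 1:
        raise ValueError("stratified split needs >= 1 positive in some task")

    rng = np.random.default_rng(seed)
    targets = list(_target_sizes(n))
    assign = np.full(n, -1, dtype=np.int64)  # -1 unassigned; 0 train, 1 valid, 2 test
    sizes = [0, 0, 0]

    def capacity(fold: int) -> int:
        return targets[fold] - sizes[fold]

    order = np.argsort(pos_counts, kind="stable")
    for t in order:
        total_pos = int(pos_counts[t])
        if total_pos == 0:
            warnings.warn(f"task {labels.task_names[t]!r} has no positives; "
                          "no stratification constraint applied")
            continue
        pending = np.flatnonzero((y[:, t] == 1) & (assign == -1))
        if total_pos <= 2:
            warnings.warn(f"task {labels.task_names[t]!r} has only {total_pos} "
                          "positive(s); placing them in the training fold")
            for i in pending:
                fold = 0 if capacity(0) > 0 else int(np.argmax([capacity(f) for f in range(3)]))
                assign[i] = fold
                sizes[fold] += 1
            continue
        pending = rng.permutation(pending)
        k = len(pending)
        n_v = int(np.floor(FRACTIONS[1] * k))
        n_te = int(np.floor(FRACTIONS[2] * k))
        folds = np.zeros(k, dtype=np.int64)
        folds[:n_v] = 1
        folds[n_v:n_v + n_te] = 2
        # bump: every fold must hold >= 1 positive of this task overall
        have = [int(((assign == f) & (y[:, t] == 1)).sum()) for f in range(3)]
        for f in range(3):
            have[f] += int((folds == f).sum())
        for f in range(3):
            if have[f] == 0 and capacity(f) > 0:
                donor = int(np.argmax(have))
                donors = np.flatnonzero(folds == donor)
                if donors.size and have[donor] > 1:
                    folds[donors[0]] = f
                    have[f] += 1
                    have[donor] -= 1
        # respect capacities: overflowing assignments spill to the emptiest fold
        for i, f in zip(pending, folds):
            f = int(f)
            if capacity(f) <= 0:
                f = int(np.argmax([capacity(g) for g in range(3)]))
            assign[i] = f
            sizes[f] += 1

    remaining = rng.permutation(np.flatnonzero(assign == -1))
    pos = 0
    for f in range(3):
        take = min(capacity(f), len(remaining) - pos)
        for i in remaining[pos:pos + take]:
            assign[i] = f
        sizes[f] += take
        pos += take
    for i in remaining[pos:]:  # rounding leftovers
        f = int(np.argmax([capacity(g) for g in range(3)]))
        assign[i] = f
        sizes[f] += 1

    return SplitResult(np.flatnonzero(assign == 0), np.flatnonzero(assign == 1),
                       np.flatnonzero(assign == 2), strategy="random_stratified",
                       seed=seed)


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold (ring systems + linkers) of a molecule.

    Acyclic molecules return the empty string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(smiles_list: list[str], seed: int = 0,
                   merge_acyclic: bool = True) -> SplitResult:
    """Group molecules by Bemis-Murcko scaffold; whole groups share a fold.

    Groups are sorted by size descending (ties by scaffold string) and
    assigned greedily: train until it holds >= 80% of samples, then valid
    until >= 10%, remainder to test.  With ``merge_acyclic`` (default) all
    acyclic molecules form one shared pseudo-scaffold group; otherwise each
    is its own singleton.
    """
    n = len(smiles_list)
    if n < 10:
        raise ValueError(f"need n >= 10 samples to split, got {n}")
    groups: dict[str, list[int]] = {}
    for i, smi in enumerate(smiles_list):
        scaf = bemis_murcko_scaffold(smi)
        if scaf == "" and not merge_acyclic:
            scaf = f"__acyclic_{i}__"
        groups.setdefault(scaf, []).append(i)

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n_train, n_valid, _ = _target_sizes(n)
    folds: list[list[int]] = [[], [], []]
    for _, members in ordered:
        if len(folds[0]) < n_train:
            folds[0].extend(members)
        elif len(folds[1]) < n_valid:
            folds[1].extend(members)
        else:
            folds[2].extend(members)
    return SplitResult(np.array(sorted(folds[0])), np.array(sorted(folds[1])),
                       np.array(sorted(folds[2])), strategy="scaffold", seed=seed)
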