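"""Model/Results facade over the library.

:class:`MeridianGCN` is built from data (graphs + label matrix, or a compound
table DataFrame); :meth:`MeridianGCN.fit` runs focal-loss training and returns
a :class:`GCNResults` carrying the fitted parameters, the training history,
prediction and evaluation methods and a ``summary()`` table.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .chem_io import AtomFeatureSpec, LabelMatrix, MolGraph, smiles_to_graph
from .evaluation import EvalReport, evaluate_predictions, label_cosine_matrix
from .graph_net import GCNParams, GraphBatch, forward, load_params, save_params
from .splits import (
    SplitResult,
    index_split,
    random_split,
    scaffold_split,
    stratified_split,
)
from .training import FitConfig, TrainHistory, fit as _fit

__all__ = ["MeridianGCN", "GCNResults"]


class MeridianGCN:
    """Multi-task molecular classifier with degree-indexed graph convolutions.

    Parameters
    ----------
    graphs : parsed molecular graphs, one per compound.
    labels : the binary compounds x tasks supervision matrix.
    smiles : optional SMILES aligned with ``graphs`` (required for scaffold
        splitting).
    """

    def __init__(self, graphs: list[MolGraph], labels: LabelMatrix,
                 smiles: list[str] | None = None):
        if len(graphs) != labels.n_compounds:
            raise ValueError(
                f"{len(graphs)} graphs vs {labels.n_compounds} label rows"
            )
        self.graphs = graphs
        self.labels = labels
        self.smiles = smiles if smiles is not None else [g.smiles for g in graphs]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       feature_spec: AtomFeatureSpec | None = None) -> "MeridianGCN":
        """Build from a compound table: columns ``compound_id, smiles, <task>...``."""
        task_names = [c for c in df.columns if c not in ("compound_id", "smiles")]
        labels = LabelMatrix([str(c) for c in df["compound_id"]], task_names,
                             df[task_names].to_numpy())
        smiles = list(df["smiles"])
        graphs = [smiles_to_graph(s, feature_spec) for s in smiles]
        return cls(graphs, labels, smiles)

    def split(self, strategy: str = "random_stratified", seed: int = 0) -> SplitResult:
        n = self.labels.n_compounds
        if strategy == "index":
            return index_split(n)
        if strategy == "random":
            return random_split(n, seed)
        if strategy == "random_stratified":
            return stratified_split(self.labels, seed)
        if strategy == "scaffold":
            return scaffold_split(self.smiles, seed)
        raise ValueError(f"unknown split strategy {strategy!r}")

    def fit(self, split: SplitResult | None = None,
            config: FitConfig | None = None, log_path=None) -> "GCNResults":
        config = config or FitConfig()
        split = split if split is not None else self.split(seed=config.seed)
        params, history = _fit(self.graphs, self.labels, split, config,
                               log_path=log_path)
        return GCNResults(self, params, history, split, config)


class GCNResults:
    """Fitted model: parameters, history, predictions, evaluation, summary."""

    def __init__(self, model: MeridianGCN, params: GCNParams,
                 history: TrainHistory, split: SplitResult, config: FitConfig):
        self.model = model
        self.params = params
        self.history = history
        self.split = split
        self.config = config

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, graphs: list[MolGraph] | None = None) -> np.ndarray:
        graphs = graphs if graphs is not None else self.model.graphs
        return forward(self.params, GraphBatch(graphs), mode="eval")

    def predict_smiles(self, smiles: list[str]) -> np.ndarray:
        return self.predict_proba([smiles_to_graph(s) for s in smiles])

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, subset: str = "test", threshold: float = 0.5) -> EvalReport:
        idx = getattr(self.split, subset)
        probs = self.predict_proba([self.model.graphs[i] for i in idx])
        return evaluate_predictions(self.model.labels.labels[idx], probs,
                                    self.model.labels.task_names, threshold)

    def task_cosine_similarity(self) -> tuple[np.ndarray, float]:
        return label_cosine_matrix(self.model.labels)

    # -- persistence --------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        save_params(path, self.params)

    @staticmethod
    def load_checkpoint(path) -> GCNParams:
        return load_params(path)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        buf = io.StringIO()
        cfg, lab = self.config, self.model.labels
        buf.write("MeridianGCN fit results\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"compounds: {lab.n_compounds}   tasks: {lab.n_tasks}   "
                  f"split: {self.split.strategy} (seed {self.split.seed})\n")
        buf.write(f"depth {cfg.depth}  width {cfg.width}  batch {cfg.batch_size}  "
                  f"epochs {cfg.epochs}  lr {cfg.learning_rate}  "
                  f"gamma {cfg.gamma}  alpha {cfg.alpha}\n")
        if self.history.best_epoch is not None and self.history.valid_macro_auc:
            buf.write(f"best epoch: {self.history.best_epoch + 1} "
                      f"(valid macro-AUC "
                      f"{self.history.valid_macro_auc[self.history.best_epoch]:.4f})\n")
        for subset in ("train", "valid", "test"):
            try:
                rep = self.evaluate(subset)
                buf.write(f"\n[{subset}] macro ROC-AUC: {rep.macro_auc:.4f}\n")
                buf.write(rep.to_frame().to_string(index=False,
                                                   float_format="%.4f") + "\n")
            except Exception as exc:  # e.g. empty fold, all-undefined AUC
                buf.write(f"\n[{subset}] not evaluable: {exc}\n")
        return buf.getvalue()
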