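"""Confusion matrices, ROC-AUC (per task and macro) and label cosine similarity.

ROC-AUC is computed as the normalized Mann-Whitney U statistic — the
probability that a randomly chosen positive is scored above a randomly chosen
negative, with ties receiving half credit.  Tasks whose evaluation slice has
only one class report an undefined AUC (``None``) rather than an imputed
score, and the macro average skips them; with very rare tasks this is the
honest convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "UndefinedAUCError",
    "TaskEval",
    "EvalReport",
    "confusion_matrix",
    "roc_auc",
    "macro_auc",
    "evaluate_predictions",
    "label_cosine_matrix",
]


class UndefinedAUCError(ValueError):
    """ROC-AUC is undefined when only one class is present."""


def confusion_matrix(y, y_hat, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at the given probability threshold (positive iff >=)."""
    y = np.asarray(y)
    s = np.asarray(y_hat)
    if y.shape != s.shape or y.size == 0:
        raise ValueError("labels and scores must have equal, non-zero length")
    pred = s >= threshold
    tp = int(((y == 1) & pred).sum())
    fp = int(((y == 0) & pred).sum())
    tn = int(((y == 0) & ~pred).sum())
    fn = int(((y == 1) & ~pred).sum())
    return tp, fp, tn, fn


def roc_auc(y, scores) -> float:
    """Mann-Whitney ROC-AUC with midrank tie handling.

    Equals (#(pos,neg) pairs with score_pos > score_neg + 0.5 * ties) /
    (n_pos * n_neg).  Raises :class:`UndefinedAUCError` on single-class input.
    """
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(f"need both classes, got {n_pos} pos / {n_neg} neg")
    ranks = rankdata(s)  # midranks
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class TaskEval:
    task: str
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None
    n: int


@dataclass
class EvalReport:
    tasks: list[TaskEval]

    @property
    def macro_auc(self) -> float:
        return macro_auc(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(task=t.task, TP=t.tp, FP=t.fp, TN=t.tn, FN=t.fn,
                     AUC=t.auc if t.auc is not None else np.nan, n=t.n)
                for t in self.tasks
            ]
        )


def macro_auc(report: EvalReport) -> float:
    """Unweighted mean AUC over tasks with a defined AUC."""
    defined = [t.auc for t in report.tasks if t.auc is not None]
    if not defined:
        raise UndefinedAUCError("no task has a defined AUC")
    return float(np.mean(defined))


def evaluate_predictions(y_matrix, prob_matrix, task_names: list[str],
                         threshold: float = 0.5) -> EvalReport:
    """Per-task confusion matrices and AUCs for a prediction matrix."""
    y = np.asarray(y_matrix)
    p = np.asarray(prob_matrix)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    tasks = []
    for t, name in enumerate(task_names):
        tp, fp, tn, fn = confusion_matrix(y[:, t], p[:, t], threshold)
        try:
            auc = roc_auc(y[:, t], p[:, t])
        except UndefinedAUCError:
            auc = None
        tasks.append(TaskEval(name, tp, fp, tn, fn, auc, y.shape[0]))
    return EvalReport(tasks)


def label_cosine_matrix(labels) -> tuple[np.ndarray, float]:
    """Pairwise cosine similarity between task label columns.

    Returns the symmetric similarity matrix (NaN where a column is all-zero,
    with a warning-free flagging via NaN) and the mean of the defined
    off-diagonal entries.
    """
    y = np.asarray(getattr(labels, "labels", labels), dtype=float)
    norms = np.linalg.norm(y, axis=0)
    gram = y.T @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = gram / np.outer(norms, norms)
    sim[:, norms == 0] = np.nan
    sim[norms == 0, :] = np.nan
    np.fill_diagonal(sim, np.where(norms > 0, 1.0, np.nan))
    off = sim[~np.eye(sim.shape[0], dtype=bool)]
    off_mean = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    return sim, off_mean
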