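"""Focal-loss objective and the mini-batch Adam training loop.

The focal loss reshapes binary cross entropy with a modulating factor that
down-weights easy examples::

    L(y=1) = -alpha * (1 - p)^gamma * log(p)
    L(y=0) = -(1 - alpha) * p^gamma * log(1 - p)

where ``p`` is the predicted probability of the positive class, ``gamma >= 0``
controls how strongly easy examples are suppressed and ``alpha`` balances the
two classes.  With ``gamma = 0`` it reduces to (alpha-scaled) cross entropy.
Losses are averaged (not summed) over all (sample, task) cells so the
learning-rate meaning is batch-size independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_io import LabelMatrix, MolGraph
from .graph_net import (
    GCNConfig,
    GCNParams,
    GraphBatch,
    backward,
    forward,
    init_params,
)
from .splits import SplitResult

__all__ = [
    "FitConfig",
    "TrainHistory",
    "EPS_PROB",
    "focal_loss",
    "focal_loss_grad",
    "batch_loss",
    "batch_loss_grad",
    "AdamState",
    "fit",
]

#: probabilities are clamped to [EPS_PROB, 1 - EPS_PROB] before the log
EPS_PROB = 1e-7


@dataclass(frozen=True)
class FitConfig:
    """Training hyperparameters.

    The defaults are the reference operating point of the method: three
    hidden layers of 1024 neurons, mini-batches of 64, 200 epochs, Adam with
    learning rate 5e-4, and focal loss with gamma=2, alpha=0.5.
    """

    learning_rate: float = 0.0005
    batch_size: int = 64
    epochs: int = 200
    gamma: float = 2.0
    alpha: float = 0.5
    depth: int = 3
    width: int = 1024
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    #: "final" returns the last-epoch parameters; "best_valid" returns those
    #: of the epoch with the best validation macro-AUC.  Final is the default:
    #: on heavily imbalanced tasks the validation fold may hold only a couple
    #: of positives, making its AUC too coarse to select an epoch reliably.
    model_selection: str = "final"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if self.model_selection not in ("final", "best_valid"):
            raise ValueError("model_selection must be 'final' or 'best_valid'")


@dataclass
class TrainHistory:
    """Per-epoch record of mean training loss and validation macro ROC-AUC."""

    train_loss: list[float] = field(default_factory=list)
    valid_macro_auc: list[float] = field(default_factory=list)
    best_epoch: int | None = None

    def as_log_lines(self) -> list[str]:
        return [
            f"epoch {e + 1}\tloss {l:.6f}\tvalid_macro_auc {a:.4f}"
            for e, (l, a) in enumerate(zip(self.train_loss, self.valid_macro_auc))
        ]


def _validate_labels(y: np.ndarray) -> None:
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")


def focal_loss(y, y_hat, gamma: float = 2.0, alpha: float = 0.5) -> np.ndarray:
    """Element-wise focal loss; ``y`` in {0,1}, ``y_hat`` probabilities.

    Natural logarithm; probabilities clamped away from {0, 1} by EPS_PROB.
    """
    y = np.asarray(y, dtype=float)
    _validate_labels(y)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS_PROB, 1.0 - EPS_PROB)
    pos = -alpha * (1.0 - p) ** gamma * np.log(p)
    neg = -(1.0 - alpha) * p ** gamma * np.log(1.0 - p)
    return np.where(y == 1, pos, neg)


def focal_loss_grad(y, y_hat, gamma: float = 2.0, alpha: float = 0.5) -> np.ndarray:
    """dL/dp of the focal loss, evaluated at clamped p (clamp treated flat)."""
    y = np.asarray(y, dtype=float)
    _validate_labels(y)
    p_raw = np.asarray(y_hat, dtype=float)
    p = np.clip(p_raw, EPS_PROB, 1.0 - EPS_PROB)
    if gamma == 0.0:
        dpos = -alpha / p
        dneg = (1.0 - alpha) / (1.0 - p)
    else:
        dpos = alpha * (gamma * (1.0 - p) ** (gamma - 1.0) * np.log(p)
                        - (1.0 - p) ** gamma / p)
        dneg = -(1.0 - alpha) * (gamma * p ** (gamma - 1.0) * np.log(1.0 - p)
                                 - p ** gamma / (1.0 - p))
    grad = np.where(y == 1, dpos, dneg)
    # gradient is zero where the clamp is active
    return np.where((p_raw > EPS_PROB) & (p_raw < 1.0 - EPS_PROB), grad, 0.0)


def batch_loss(y_matrix, y_hat_matrix, gamma: float = 2.0, alpha: float = 0.5) -> float:
    """Mean focal loss over all (sample, task) cells."""
    y = np.asarray(y_matrix, dtype=float)
    p = np.asarray(y_hat_matrix, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs predictions {p.shape}")
    return float(focal_loss(y, p, gamma, alpha).mean())


def batch_loss_grad(y_matrix, y_hat_matrix, gamma: float = 2.0,
                    alpha: float = 0.5) -> np.ndarray:
    """d(batch_loss)/d(y_hat): element-wise gradient scaled by 1/num_cells."""
    y = np.asarray(y_matrix, dtype=float)
    p = np.asarray(y_hat_matrix, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs predictions {p.shape}")
    return focal_loss_grad(y, p, gamma, alpha) / y.size


class AdamState:
    """First/second-moment accumulators for one named-tensor collection."""

    def __init__(self, tensors: dict[str, np.ndarray]):
        self.m = {k: np.zeros_like(v) for k, v in tensors.items()}
        self.v = {k: np.zeros_like(v) for k, v in tensors.items()}
        self.t = 0

    def step(self, tensors: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float, beta1: float = 0.9, beta2: float = 0.999,
             eps: float = 1e-8) -> None:
        self.t += 1
        bc1 = 1.0 - beta1 ** self.t
        bc2 = 1.0 - beta2 ** self.t
        for k, w in tensors.items():
            g = grads[k]
            self.m[k] = beta1 * self.m[k] + (1 - beta1) * g
            self.v[k] = beta2 * self.v[k] + (1 - beta2) * g * g
            w -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + eps)


def fit(graphs: list[MolGraph], labels: LabelMatrix, split: SplitResult,
        config: FitConfig, log_path=None,
        init: GCNParams | None = None) -> tuple[GCNParams, TrainHistory]:
    """Train the multi-task GCN with mini-batch Adam on the focal loss.

    All randomness (weight initialization, per-epoch shuffling) derives from
    ``config.seed``, so two runs with the same inputs produce the same
    parameter trajectory on one platform.  After each epoch the validation
    macro ROC-AUC is computed in eval mode and the best epoch recorded in the
    history.  By default the final-epoch parameters are returned; with
    ``model_selection="best_valid"`` the best-validation-epoch parameters are
    returned instead (final epoch if no validation AUC is ever defined).
    Tasks without training positives are retained with a warning — the loss
    stays defined.
    """
    from .evaluation import roc_auc  # late import to avoid a cycle

    y = labels.labels.astype(float)
    train_idx = np.asarray(split.train, dtype=np.int64)
    valid_idx = np.asarray(split.valid, dtype=np.int64)
    y_train = y[train_idx]
    pos_per_task = y_train.sum(axis=0)
    if not ((pos_per_task >= 1) & (pos_per_task < len(train_idx))).any():
        raise ValueError("training set needs >= 1 positive and >= 1 negative "
                         "in at least one task")
    for t, c in enumerate(pos_per_task):
        if c == 0:
            warnings.warn(f"task {labels.task_names[t]!r} has no training positives")

    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    gcn_cfg = GCNConfig(feature_dim=graphs[0].feature_dim, num_tasks=labels.n_tasks,
                        depth=config.depth, width=config.width)
    params = init.copy() if init is not None else init_params(gcn_cfg, init_rng)
    adam = AdamState(params.trainable())
    history = TrainHistory()

    valid_batch = GraphBatch([graphs[i] for i in valid_idx]) if valid_idx.size else None
    log_fh = open(log_path, "w") if log_path is not None else None
    best_params = params.copy()
    best_auc = -np.inf
    try:
        for epoch in range(config.epochs):
            order = shuffle_rng.permutation(len(train_idx))
            losses = []
            for start in range(0, len(order), config.batch_size):
                chunk = train_idx[order[start:start + config.batch_size]]
                batch = GraphBatch([graphs[i] for i in chunk])
                probs, cache = forward(params, batch, mode="train", return_cache=True)
                yb = y[chunk]
                losses.append(batch_loss(yb, probs, config.gamma, config.alpha))
                dprobs = batch_loss_grad(yb, probs, config.gamma, config.alpha)
                dlogits = dprobs * probs * (1.0 - probs)
                grads = backward(params, batch, cache, dlogits)
                adam.step(params.trainable(), grads, config.learning_rate,
                          config.adam_beta1, config.adam_beta2, config.adam_eps)
            mean_loss = float(np.mean(losses)) if losses else float("nan")

            valid_auc = float("nan")
            if valid_batch is not None:
                vp = forward(params, valid_batch, mode="eval")
                aucs = []
                for t in range(labels.n_tasks):
                    yt = y[valid_idx, t]
                    if 0 < yt.sum() < len(yt):
                        aucs.append(roc_auc(yt, vp[:, t]))
                if aucs:
                    valid_auc = float(np.mean(aucs))
            history.train_loss.append(mean_loss)
            history.valid_macro_auc.append(valid_auc)
            if log_fh is not None:
                log_fh.write(f"epoch {epoch + 1}\tloss {mean_loss:.6f}"
                             f"\tvalid_macro_auc {valid_auc:.4f}\n")
            # ties resolved toward the later epoch: with few validation
            # positives the AUC is coarsely discrete, and among equally
            # scoring epochs the more-converged parameters are preferred
            if np.isfinite(valid_auc) and valid_auc >= best_auc:
                best_auc = valid_auc
                history.best_epoch = epoch
                if config.model_selection == "best_valid":
                    best_params = params.copy()
    finally:
        if log_fh is not None:
            log_fh.close()

    if history.best_epoch is None and config.epochs:
        history.best_epoch = config.epochs - 1
    if config.model_selection == "best_valid" and best_auc > -np.inf:
        return best_params, history
    return params, history
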