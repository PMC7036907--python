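"""Degree-indexed graph convolutional network: forward pass and analytic gradients.

The architecture follows the neural-fingerprint family of graph networks:

* graph convolution with weight sharing by node degree — node ``v`` with
  (clipped) degree ``d`` is updated as
  ``h'(v) = ReLU( W_d . (h(v) + sum_{u in N(v)} h(u)) + b_d )``,
  i.e. the same degree-indexed matrix multiplies the self term and the
  neighbor sum;
* node-level batch normalization over all nodes of the mini-batch;
* neighborhood max-pooling over the closed neighborhood ``{v} u N(v)``;
* a degree-weighted graph-gather readout
  ``g = tanh( sum_v Phi_{deg(v)} . h(v) + beta )`` producing one embedding
  per molecule (the bias is a single shared vector added after the node sum);
* a dense multi-task head with element-wise sigmoid.

No autodiff framework is used: backpropagation through every layer is derived
and implemented by hand in NumPy, and verified against central finite
differences in the test suite.  All arithmetic is float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chem_io import MAX_DEGREE, MolGraph

__all__ = [
    "GCNConfig",
    "GCNParams",
    "GraphBatch",
    "init_params",
    "graph_conv",
    "node_batch_norm",
    "graph_max_pool",
    "graph_gather",
    "forward",
    "backward",
    "save_params",
    "load_params",
    "CHECKPOINT_FORMAT_VERSION",
]

N_DEGREES = MAX_DEGREE + 1  # degree-indexed parameter slots 0..6
CHECKPOINT_FORMAT_VERSION = 1


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class GCNConfig:
    """Architecture hyperparameters.

    Defaults: 3 hidden layers of 1024 neurons; the gather dimension equals the
    hidden width.  ``tie_self_neighbor=True`` applies the same degree-indexed
    matrix to the self term and the neighbor sum (the printed update rule);
    setting it False gives each layer separate self/neighbor matrices for
    ablation.
    """

    feature_dim: int
    num_tasks: int
    depth: int = 3
    width: int = 1024
    gather_dim: int | None = None
    tie_self_neighbor: bool = True
    bn_eps: float = 1e-5
    bn_momentum: float = 0.9

    @property
    def gdim(self) -> int:
        return self.gather_dim if self.gather_dim is not None else self.width


@dataclass
class GCNParams:
    """All learnable tensors plus batch-norm running statistics.

    Degree-indexed collections always cover degrees 0..MAX_DEGREE; parameters
    for degrees absent from the data exist but stay at initialization.
    """

    config: GCNConfig
    conv_W: list[np.ndarray]        # per layer: (N_DEGREES, out, in)
    conv_Wn: list[np.ndarray] | None  # separate neighbor matrices (untied mode)
    conv_b: list[np.ndarray]        # per layer: (N_DEGREES, out)
    bn_scale: list[np.ndarray]      # per layer: (out,)
    bn_shift: list[np.ndarray]
    bn_run_mean: list[np.ndarray]
    bn_run_var: list[np.ndarray]
    gather_W: np.ndarray            # (N_DEGREES, gdim, width)
    gather_b: np.ndarray            # (gdim,)
    head_W: np.ndarray              # (num_tasks, gdim)
    head_b: np.ndarray              # (num_tasks,)

    def copy(self) -> "GCNParams":
        return GCNParams(
            config=self.config,
            conv_W=[w.copy() for w in self.conv_W],
            conv_Wn=None if self.conv_Wn is None else [w.copy() for w in self.conv_Wn],
            conv_b=[b.copy() for b in self.conv_b],
            bn_scale=[g.copy() for g in self.bn_scale],
            bn_shift=[b.copy() for b in self.bn_shift],
            bn_run_mean=[m.copy() for m in self.bn_run_mean],
            bn_run_var=[v.copy() for v in self.bn_run_var],
            gather_W=self.gather_W.copy(),
            gather_b=self.gather_b.copy(),
            head_W=self.head_W.copy(),
            head_b=self.head_b.copy(),
        )

    def trainable(self) -> dict[str, np.ndarray]:
        """Named views of every trainable tensor (running stats excluded)."""
        out: dict[str, np.ndarray] = {}
        for t in range(self.config.depth):
            out[f"conv{t}.W"] = self.conv_W[t]
            if self.conv_Wn is not None:
                out[f"conv{t}.Wn"] = self.conv_Wn[t]
            out[f"conv{t}.b"] = self.conv_b[t]
            out[f"bn{t}.scale"] = self.bn_scale[t]
            out[f"bn{t}.shift"] = self.bn_shift[t]
        out["gather.W"] = self.gather_W
        out["gather.b"] = self.gather_b
        out["head.W"] = self.head_W
        out["head.b"] = self.head_b
        return out


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def init_params(config: GCNConfig, rng: np.random.Generator) -> GCNParams:
    """Scaled-uniform (fan-in) weight initialization, zero biases."""
    conv_W, conv_Wn, conv_b = [], [], []
    bn_scale, bn_shift, bn_mean, bn_var = [], [], [], []
    in_dim = config.feature_dim
    for _ in range(config.depth):
        conv_W.append(_fan_in_uniform(rng, (N_DEGREES, config.width, in_dim), in_dim))
        if not config.tie_self_neighbor:
            conv_Wn.append(_fan_in_uniform(rng, (N_DEGREES, config.width, in_dim), in_dim))
        conv_b.append(np.zeros((N_DEGREES, config.width)))
        bn_scale.append(np.ones(config.width))
        bn_shift.append(np.zeros(config.width))
        bn_mean.append(np.zeros(config.width))
        bn_var.append(np.ones(config.width))
        in_dim = config.width
    gather_W = _fan_in_uniform(rng, (N_DEGREES, config.gdim, config.width), config.width)
    head_W = _fan_in_uniform(rng, (config.num_tasks, config.gdim), config.gdim)
    return GCNParams(
        config=config,
        conv_W=conv_W,
        conv_Wn=conv_Wn if not config.tie_self_neighbor else None,
        conv_b=conv_b,
        bn_scale=bn_scale,
        bn_shift=bn_shift,
        bn_run_mean=bn_mean,
        bn_run_var=bn_var,
        gather_W=gather_W,
        gather_b=np.zeros(config.gdim),
        head_W=head_W,
        head_b=np.zeros(config.num_tasks),
    )


class GraphBatch:
    """A list of molecular graphs packed into flat node arrays.

    Nodes of all molecules are concatenated; ``mol_index`` records molecule
    membership.  Neighbor lists are padded to rectangular arrays: ``nbr_pad``
    pads with a phantom node index ``num_nodes`` (whose features are zero),
    ``closed_pad`` holds the closed neighborhood ``[v, u_1, ..]`` padded with
    ``v`` itself (harmless under element-wise max).
    """

    def __init__(self, graphs: list[MolGraph]):
        if not graphs:
            raise ValueError("empty batch")
        feats = [g.atom_features for g in graphs]
        dims = {f.shape[1] for f in feats}
        if len(dims) != 1:
            raise ShapeError(f"inconsistent feature dims in batch: {sorted(dims)}")
        self.features = np.concatenate(feats).astype(np.float64)
        self.n_nodes = self.features.shape[0]
        self.n_mols = len(graphs)
        sizes = np.array([g.num_atoms for g in graphs], dtype=np.int64)
        self.mol_index = np.repeat(np.arange(self.n_mols, dtype=np.int64), sizes)
        self.mol_starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.degrees = np.minimum(
            np.concatenate([g.degrees for g in graphs]), MAX_DEGREE
        ).astype(np.int64)

        # per-graph padded neighbor tables are built once and cached on the
        # graph; batch assembly only shifts node ids and pads to a common width
        blocks = []
        for g in graphs:
            packed = getattr(g, "_packed", None)
            if packed is None:
                n = g.num_atoms
                w = max(int(g.degrees.max(initial=0)), 1)
                nbr = np.full((n, w), n, dtype=np.int64)  # n = local dummy slot
                closed = np.empty((n, w + 1), dtype=np.int64)
                for v, nbrs in enumerate(g.neighbors):
                    nbr[v, : len(nbrs)] = nbrs
                    closed[v, 0] = v
                    closed[v, 1 : 1 + len(nbrs)] = nbrs
                    closed[v, 1 + len(nbrs):] = v
                packed = (nbr, closed)
                g._packed = packed
            blocks.append(packed)
        width = max(b[0].shape[1] for b in blocks)
        nbr_pad = np.full((self.n_nodes, width), self.n_nodes, dtype=np.int64)
        closed_pad = np.empty((self.n_nodes, width + 1), dtype=np.int64)
        for g, off, (nbr, closed) in zip(graphs, self.mol_starts, blocks):
            n, w = nbr.shape
            rows = slice(off, off + n)
            nbr_pad[rows, :w] = np.where(nbr == n, self.n_nodes, nbr + off)
            closed_pad[rows, : w + 1] = closed + off
            if w < width:  # pad closed neighborhoods with the node itself
                closed_pad[rows, w + 1:] = (closed[:, :1] + off)
        self.nbr_pad = nbr_pad
        self.closed_pad = closed_pad
        self.deg_index = [np.flatnonzero(self.degrees == d) for d in range(N_DEGREES)]

    def neighbor_sum(self, h: np.ndarray) -> np.ndarray:
        """sum_{u in N(v)} h(u) for every node v (phantom row contributes zero)."""
        padded = np.vstack([h, np.zeros((1, h.shape[1]))])
        return padded[self.nbr_pad].sum(axis=1)


def _degree_affine(batch: GraphBatch, x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z(v) = W_{deg(v)} x(v) + b_{deg(v)} computed per degree bucket."""
    out = np.empty((batch.n_nodes, W.shape[1]))
    for d in range(N_DEGREES):
        idx = batch.deg_index[d]
        if idx.size:
            out[idx] = x[idx] @ W[d].T + b[d]
    return out


# ---------------------------------------------------------------------------
# public layer operations (forward only; used standalone and in tests)
# ---------------------------------------------------------------------------

def graph_conv(state: np.ndarray, batch: GraphBatch, W: np.ndarray, b: np.ndarray,
               Wn: np.ndarray | None = None) -> np.ndarray:
    """One degree-indexed graph convolution: ReLU(W_d (h(v)+sum h(u)) + b_d).

    With ``Wn`` given, the neighbor sum gets its own matrix (untied ablation).
    """
    if state.shape[0] != batch.n_nodes:
        raise ShapeError(f"state has {state.shape[0]} rows, batch has {batch.n_nodes} nodes")
    if W.shape[2] != state.shape[1]:
        raise ShapeError(f"conv expects input dim {W.shape[2]}, state has {state.shape[1]}")
    nsum = batch.neighbor_sum(state)
    if Wn is None:
        z = _degree_affine(batch, state + nsum, W, b)
    else:
        z = _degree_affine(batch, state, W, b) + _degree_affine(
            batch, nsum, Wn, np.zeros_like(b)
        )
    return np.maximum(z, 0.0)


def node_batch_norm(state: np.ndarray, scale: np.ndarray, shift: np.ndarray,
                    run_mean: np.ndarray, run_var: np.ndarray,
                    mode: str = "eval", eps: float = 1e-5,
                    momentum: float = 0.9) -> np.ndarray:
    """Node-level batch normalization over all nodes of the batch.

    Train mode normalizes each channel to zero mean / unit (population)
    variance over the whole node batch, applies the learned affine, and
    updates the running statistics in place.  Eval mode uses running stats.
    """
    if mode == "train":
        if state.shape[0] < 2:
            raise ValueError("batch normalization needs >= 2 nodes in train mode")
        mean = state.mean(axis=0)
        var = state.var(axis=0)
        run_mean *= momentum
        run_mean += (1 - momentum) * mean
        run_var *= momentum
        run_var += (1 - momentum) * var
    elif mode == "eval":
        mean, var = run_mean, run_var
    else:
        raise ValueError(f"unknown mode {mode!r}")
    xhat = (state - mean) / np.sqrt(var + eps)
    return scale * xhat + shift


def graph_max_pool(state: np.ndarray, batch: GraphBatch) -> np.ndarray:
    """Element-wise maximum over each node's closed neighborhood {v} u N(v)."""
    return state[batch.closed_pad].max(axis=1)


def graph_gather(state: np.ndarray, batch: GraphBatch, Phi: np.ndarray,
                 beta: np.ndarray) -> np.ndarray:
    """g_m = tanh( sum_{v in mol m} Phi_{deg(v)} h(v) + beta ), one row per molecule."""
    if Phi.shape[2] != state.shape[1]:
        raise ShapeError(f"gather expects input dim {Phi.shape[2]}, state has {state.shape[1]}")
    u = _degree_affine(batch, state, Phi, np.zeros((N_DEGREES, Phi.shape[1])))
    pre = np.add.reduceat(u, batch.mol_starts, axis=0)
    return np.tanh(pre + beta)


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def forward(params: GCNParams, batch: GraphBatch, mode: str = "eval",
            return_cache: bool = False):
    """Full forward pass: [conv -> batch norm -> max pool] x depth, gather, head.

    Returns the (n_mols, num_tasks) probability matrix; with
    ``return_cache=True`` also the intermediates needed by :func:`backward`.
    In train mode batch-norm running statistics in ``params`` are updated.
    """
    cfg = params.config
    if batch.features.shape[1] != cfg.feature_dim:
        raise ShapeError(
            f"batch feature dim {batch.features.shape[1]} != configured {cfg.feature_dim}"
        )
    h = batch.features
    layer_caches = []
    for t in range(cfg.depth):
        try:
            nsum = batch.neighbor_sum(h)
            if params.conv_Wn is None:
                s = h + nsum
                z = _degree_affine(batch, s, params.conv_W[t], params.conv_b[t])
                s_self = None
            else:
                s = nsum
                s_self = h
                z = _degree_affine(batch, h, params.conv_W[t], params.conv_b[t]) + \
                    _degree_affine(batch, nsum, params.conv_Wn[t],
                                   np.zeros_like(params.conv_b[t]))
            a = np.maximum(z, 0.0)
            if mode == "train":
                if batch.n_nodes < 2:
                    raise ValueError("batch normalization needs >= 2 nodes in train mode")
                mean = a.mean(axis=0)
                var = a.var(axis=0)
                params.bn_run_mean[t] *= cfg.bn_momentum
                params.bn_run_mean[t] += (1 - cfg.bn_momentum) * mean
                params.bn_run_var[t] *= cfg.bn_momentum
                params.bn_run_var[t] += (1 - cfg.bn_momentum) * var
            else:
                mean = params.bn_run_mean[t]
                var = params.bn_run_var[t]
            invstd = 1.0 / np.sqrt(var + cfg.bn_eps)
            xhat = (a - mean) * invstd
            bn_out = params.bn_scale[t] * xhat + params.bn_shift[t]
            member_vals = bn_out[batch.closed_pad]          # (N, k, C)
            pooled = member_vals.max(axis=1)
            if return_cache:
                # first member attaining the max receives the gradient
                slot = (member_vals == pooled[:, None, :]).argmax(axis=1)
                pool_src = np.take_along_axis(
                    batch.closed_pad[:, :, None], slot[:, None, :], axis=1
                )[:, 0, :]                                  # (N, C) source node ids
            else:
                pool_src = None
        except ShapeError as e:
            raise ShapeError(f"layer {t}: {e}") from None
        layer_caches.append(
            dict(h_in=h, s=s, s_self=s_self, z=z, a=a, xhat=xhat, invstd=invstd,
                 pool_src=pool_src, mode=mode)
        )
        h = pooled

    u = _degree_affine(batch, h, params.gather_W,
                       np.zeros((N_DEGREES, cfg.gdim)))
    pre = np.add.reduceat(u, batch.mol_starts, axis=0)
    g = np.tanh(pre + params.gather_b)
    logits = g @ params.head_W.T + params.head_b
    probs = _sigmoid(logits)
    if not return_cache:
        return probs
    cache = dict(layers=layer_caches, h_last=h, g=g, logits=logits, probs=probs)
    return probs, cache


def backward(params: GCNParams, batch: GraphBatch, cache: dict,
             dlogits: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradients of a scalar loss w.r.t. every trainable tensor.

    ``dlogits`` is dLoss/dlogits, shape (n_mols, num_tasks).  Returns a dict
    keyed like :meth:`GCNParams.trainable`.
    """
    cfg = params.config
    grads: dict[str, np.ndarray] = {}

    g = cache["g"]
    grads["head.W"] = dlogits.T @ g
    grads["head.b"] = dlogits.sum(axis=0)
    dg = dlogits @ params.head_W
    dpre = dg * (1.0 - g * g)                       # tanh'
    grads["gather.b"] = dpre.sum(axis=0)

    h_last = cache["h_last"]
    dpre_node = dpre[batch.mol_index]               # (N, gdim)
    dGather = np.zeros_like(params.gather_W)
    dh = np.zeros_like(h_last)
    for d in range(N_DEGREES):
        idx = batch.deg_index[d]
        if idx.size:
            dGather[d] = dpre_node[idx].T @ h_last[idx]
            dh[idx] = dpre_node[idx] @ params.gather_W[d]
    grads["gather.W"] = dGather

    for t in reversed(range(cfg.depth)):
        lc = cache["layers"][t]
        # max-pool: route each channel's gradient to its argmax source node
        n, c = dh.shape
        flat_idx = lc["pool_src"] * c + np.arange(c)
        dbn = np.bincount(flat_idx.ravel(), weights=dh.ravel(),
                          minlength=n * c).reshape(n, c)
        # batch norm
        if lc["mode"] == "train":
            n = batch.n_nodes
            xhat, invstd = lc["xhat"], lc["invstd"]
            grads[f"bn{t}.scale"] = (dbn * xhat).sum(axis=0)
            grads[f"bn{t}.shift"] = dbn.sum(axis=0)
            dxhat = dbn * params.bn_scale[t]
            da = (invstd / n) * (
                n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
        else:
            invstd = lc["invstd"]
            grads[f"bn{t}.scale"] = (dbn * lc["xhat"]).sum(axis=0)
            grads[f"bn{t}.shift"] = dbn.sum(axis=0)
            da = dbn * params.bn_scale[t] * invstd
        dz = da * (lc["z"] > 0)
        # degree-indexed affine
        dW = np.zeros_like(params.conv_W[t])
        db = np.zeros_like(params.conv_b[t])
        if params.conv_Wn is None:
            s = lc["s"]  # h + neighbor sum
            ds = np.zeros_like(s)
            for d in range(N_DEGREES):
                idx = batch.deg_index[d]
                if idx.size:
                    dW[d] = dz[idx].T @ s[idx]
                    db[d] = dz[idx].sum(axis=0)
                    ds[idx] = dz[idx] @ params.conv_W[t][d]
            dh = ds + batch.neighbor_sum(ds)
        else:
            nsum, h_in = lc["s"], lc["s_self"]
            dWn = np.zeros_like(params.conv_Wn[t])
            dself = np.zeros_like(h_in)
            dnsum = np.zeros_like(nsum)
            for d in range(N_DEGREES):
                idx = batch.deg_index[d]
                if idx.size:
                    dW[d] = dz[idx].T @ h_in[idx]
                    dWn[d] = dz[idx].T @ nsum[idx]
                    db[d] = dz[idx].sum(axis=0)
                    dself[idx] = dz[idx] @ params.conv_W[t][d]
                    dnsum[idx] = dz[idx] @ params.conv_Wn[t][d]
            grads[f"conv{t}.Wn"] = dWn
            dh = dself + batch.neighbor_sum(dnsum)
        grads[f"conv{t}.W"] = dW
        grads[f"conv{t}.b"] = db
    return grads


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_params(path, params: GCNParams) -> None:
    """Write all tensors (trainable + running stats) to a single .npz container.

    Round-trips bit-exactly; carries a format-version field and the
    architecture config so a checkpoint is self-describing.
    """
    cfg = params.config
    meta = dict(
        format_version=CHECKPOINT_FORMAT_VERSION,
        feature_dim=cfg.feature_dim, num_tasks=cfg.num_tasks, depth=cfg.depth,
        width=cfg.width, gather_dim=cfg.gdim, tie_self_neighbor=cfg.tie_self_neighbor,
        bn_eps=cfg.bn_eps, bn_momentum=cfg.bn_momentum,
    )
    arrays: dict[str, np.ndarray] = {"__meta__": np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)}
    arrays.update(params.trainable())
    for t in range(cfg.depth):
        arrays[f"bn{t}.run_mean"] = params.bn_run_mean[t]
        arrays[f"bn{t}.run_var"] = params.bn_run_var[t]
    np.savez(path, **arrays)


def load_params(path) -> GCNParams:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        cfg = GCNConfig(
            feature_dim=meta["feature_dim"], num_tasks=meta["num_tasks"],
            depth=meta["depth"], width=meta["width"], gather_dim=meta["gather_dim"],
            tie_self_neighbor=meta["tie_self_neighbor"], bn_eps=meta["bn_eps"],
            bn_momentum=meta["bn_momentum"],
        )
        tied = cfg.tie_self_neighbor
        return GCNParams(
            config=cfg,
            conv_W=[data[f"conv{t}.W"] for t in range(cfg.depth)],
            conv_Wn=None if tied else [data[f"conv{t}.Wn"] for t in range(cfg.depth)],
            conv_b=[data[f"conv{t}.b"] for t in range(cfg.depth)],
            bn_scale=[data[f"bn{t}.scale"] for t in range(cfg.depth)],
            bn_shift=[data[f"bn{t}.shift"] for t in range(cfg.depth)],
            bn_run_mean=[data[f"bn{t}.run_mean"] for t in range(cfg.depth)],
            bn_run_var=[data[f"bn{t}.run_var"] for t in range(cfg.depth)],
            gather_W=data["gather.W"],
            gather_b=data["gather.b"],
            head_W=data["head.W"],
            head_b=data["head.b"],
        )
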