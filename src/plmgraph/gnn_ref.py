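"""Reference invariant message-passing network for the toy benchmarks.

The point the toy experiments make is a symmetry argument, not an
architecture benchmark: any message-passing network whose messages see
only (h_i, h_j, ||x_i - x_j||^2) is invariant to rotations, translations
and reflections of the coordinates and equivariant to node permutations,
and therefore two residues with identical features and isometric
neighbourhoods are indistinguishable.  This module provides the smallest
network with exactly those properties.

Architecture
------------
L rounds of message passing.  On edge (i, j) the message is

    m_ij = tanh(W_m [h_i ; h_j ; d_ij^2 / s] + b_m)

aggregated (sum or mean) over the in-edges of each node, followed by

    h_j <- tanh(W_u [h_j ; agg_j] + b_u).

The readout concatenates the input features with the final hidden state,
standardises, and applies a one-hidden-layer MLP (ReLU) producing either
class logits or a scalar per node.

Training keeps the geometric encoder weights frozen at their seeded
random initialisation and fits only the readout head by mini-batch Adam
(a randomised-encoder / trained-readout design in the spirit of random
feature models).  This keeps every run cheap, deterministic and exactly
reproducible on one CPU while preserving the invariances that drive the
experiment's conclusions: any positional information the head can use
must already be present in the node features or the invariant geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, ShapeError, ValidationError
from .graph_build import ProteinGraph

__all__ = ["GNNConfig", "TrainReport", "init_params", "forward", "train"]


@dataclass(frozen=True)
class GNNConfig:
    """Hyperparameters of the reference network and its training loop.

    ``head`` is 'classify' (per-node logits over ``n_classes``) or
    'regress' (per-node scalar).  ``dist_scale`` divides squared edge
    distances (angstrom^2) before they enter the message MLP so tanh
    operates in its responsive range; 100 suits CA graphs whose edges
    span roughly 4-12 angstroms.
    """

    layers: int = 2
    hidden_width: int = 64
    aggregation: str = "mean"
    head: str = "classify"
    n_classes: int | None = None
    seed: int = 0
    epochs: int = 300
    lr: float = 0.01
    batch_size: int = 2048
    head_hidden: int = 192
    dist_scale: float = 100.0

    def __post_init__(self):
        if self.layers < 1 or self.hidden_width < 1:
            raise ValidationError("layers and hidden_width must be >= 1")
        if self.aggregation not in ("sum", "mean"):
            raise ValidationError("aggregation must be 'sum' or 'mean'")
        if self.head not in ("classify", "regress"):
            raise ValidationError("head must be 'classify' or 'regress'")
        if self.head == "classify" and (self.n_classes or 0) < 1:
            raise ValidationError("classify head requires n_classes >= 1")


@dataclass
class TrainReport:
    """Outcome of one seeded training run."""

    final_train_loss: float
    eval_metric: float
    metric_name: str        # 'accuracy' for classify, 'rmse' for regress
    epochs: int
    seed: int
    params: dict = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "final_train_loss": self.final_train_loss,
            "eval_metric": self.eval_metric,
            "metric_name": self.metric_name,
            "epochs": self.epochs,
            "seed": self.seed,
        }


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in)


def init_params(cfg: GNNConfig, in_width: int,
                rng: np.random.Generator | None = None) -> dict:
    """Seeded parameter set: frozen encoder layers + readout head."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    layers = []
    h_in = in_width
    for _ in range(cfg.layers):
        layers.append({
            "W_msg": _glorot(rng, 2 * h_in + 1, cfg.hidden_width),
            "b_msg": np.zeros(cfg.hidden_width),
            "W_upd": _glorot(rng, h_in + cfg.hidden_width, cfg.hidden_width),
            "b_upd": np.zeros(cfg.hidden_width),
        })
        h_in = cfg.hidden_width
    z_width = in_width + cfg.hidden_width
    out_width = cfg.n_classes if cfg.head == "classify" else 1
    head = {
        "mu": np.zeros(z_width),
        "sd": np.ones(z_width),
        "W1": _glorot(rng, z_width, cfg.head_hidden),
        "b1": np.zeros(cfg.head_hidden),
        "W2": _glorot(rng, cfg.head_hidden, out_width),
        "b2": np.zeros(out_width),
        "y_mu": 0.0,      # regression-target affine map (regress head)
        "y_sd": 1.0,
    }
    return {"layers": layers, "head": head}


def _encode(g: ProteinGraph, cfg: GNNConfig, params: dict) -> np.ndarray:
    """Run the frozen message-passing encoder; returns [h0 ; h_L] per node."""
    h = np.asarray(g.node_feats, dtype=float)
    n = g.n_nodes
    src, dst = (g.edges[:, 0], g.edges[:, 1]) if g.n_edges else (
        np.empty(0, int), np.empty(0, int))
    diff = g.coords[src] - g.coords[dst]
    d2 = np.sum(diff * diff, axis=1, keepdims=True) / cfg.dist_scale

    h0 = h
    for layer in params["layers"]:
        if 2 * h.shape[1] + 1 != layer["W_msg"].shape[0]:
            raise ShapeError("feature width does not match encoder params")
        msg_in = np.concatenate([h[src], h[dst], d2], axis=1)
        m = np.tanh(msg_in @ layer["W_msg"] + layer["b_msg"])
        agg = np.zeros((n, m.shape[1]))
        np.add.at(agg, dst, m)              # aggregate over in-edges
        if cfg.aggregation == "mean":
            indeg = np.bincount(dst, minlength=n).astype(float)
            agg /= np.maximum(indeg, 1.0)[:, None]
        h = np.tanh(np.concatenate([h, agg], axis=1) @ layer["W_upd"]
                    + layer["b_upd"])
    return np.concatenate([h0, h], axis=1)


def _head_forward(z: np.ndarray, head: dict) -> np.ndarray:
    zs = (z - head["mu"]) / head["sd"]
    a = np.maximum(zs @ head["W1"] + head["b1"], 0.0)
    return a @ head["W2"] + head["b2"]


def forward(g: ProteinGraph, cfg: GNNConfig, params: dict) -> np.ndarray:
    """Per-node outputs: (N, C) logits for classify, (N,) for regress.

    A deterministic function of (g, params); depends on coordinates only
    through edge lengths.
    """
    if g.node_feats.shape[1] + cfg.hidden_width != params["head"]["W1"].shape[0]:
        raise ShapeError("node feature width does not match head params")
    head = params["head"]
    out = _head_forward(_encode(g, cfg, params), head)
    if cfg.head == "regress":
        return out[:, 0] * head["y_sd"] + head["y_mu"]
    return out


def train(dataset, cfg: GNNConfig, graphs: list[ProteinGraph] | None = None,
          split_eval: str = "test") -> TrainReport:
    """Fit the readout head on a toy dataset; evaluate on the held-out split.

    ``graphs`` must align 1:1 with ``dataset.chains`` and already carry
    node features; when omitted, KNN-10 graphs with one-hot residue
    features are built.  Classification labels are 1-based position
    indices; positions beyond ``n_classes`` never occur because the
    class count is set to the longest chain.  Fully reproducible from
    (dataset, cfg): all randomness flows from ``cfg.seed``.
    """
    if not dataset.chains:
        raise ValidationError("empty dataset")
    if graphs is None:
        from .graph_build import attach_features, build_graph, residue_onehot
        graphs = [
            attach_features(build_graph(coords, "knn", k=10), residue_onehot(seq))
            for coords, seq in dataset.chains
        ]
    if len(graphs) != len(dataset.chains):
        raise ShapeError("graphs must align with dataset chains")

    rng = np.random.default_rng(cfg.seed)
    in_width = graphs[0].node_feats.shape[1]
    params = init_params(cfg, in_width, rng)
    head = params["head"]

    encoded = [_encode(g, cfg, params) for g in graphs]

    def stack(split: str):
        idx = dataset.splits[split]
        z = np.concatenate([encoded[i] for i in idx], axis=0)
        y = np.concatenate([np.asarray(dataset.labels[i], dtype=float)
                            for i in idx])
        return z.astype(np.float32), y

    z_tr, y_tr = stack("train")
    z_ev, y_ev = stack(split_eval)

    mu = z_tr.mean(axis=0)
    sd = z_tr.std(axis=0)
    sd[sd < 1e-8] = 1.0
    head["mu"], head["sd"] = mu.astype(float), sd.astype(float)

    zs = (z_tr - mu) / sd
    n_tr = zs.shape[0]

    if cfg.head == "classify":
        n_classes = cfg.n_classes
        if y_tr.max() > n_classes or y_tr.min() < 1:
            raise ValidationError("labels outside [1, n_classes]")
        y_idx = y_tr.astype(int) - 1
    else:
        # standardise the regression target for optimiser conditioning;
        # predictions are mapped back to label units before evaluation
        y_mu = float(y_tr.mean())
        y_sd = float(y_tr.std()) or 1.0
        y_col = ((y_tr - y_mu) / y_sd)[:, None].astype(np.float32)

    W = {k: head[k].astype(np.float32) for k in ("W1", "b1", "W2", "b2")}
    adam_m = {k: np.zeros_like(v) for k, v in W.items()}
    adam_v = {k: np.zeros_like(v) for k, v in W.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    step = 0

    loss = np.nan
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for lo in range(0, n_tr, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            nb = len(idx)
            zb = zs[idx]
            a_pre = zb @ W["W1"] + W["b1"]
            a = np.maximum(a_pre, 0.0)
            logits = a @ W["W2"] + W["b2"]

            if cfg.head == "classify":
                yb = y_idx[idx]
                # clamp the shifted logits: exp() below -30 would only
                # add denormal-range probabilities (and denormal-speed
                # epochs)
                shifted = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(np.maximum(shifted, -30.0))
                p = e / e.sum(axis=1, keepdims=True)
                batch_loss = -np.sum(np.log(p[np.arange(nb), yb] + 1e-12))
                dlogits = p
                dlogits[np.arange(nb), yb] -= 1.0
                dlogits /= nb
            else:
                diff = logits - y_col[idx]
                batch_loss = np.sum(diff ** 2)
                dlogits = 2.0 * diff / nb
            epoch_loss += float(batch_loss)

            if not np.isfinite(batch_loss):
                raise DivergenceError(epoch)

            grads = {
                "W2": a.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            da = dlogits @ W["W2"].T
            da[a_pre <= 0] = 0.0
            grads["W1"] = zb.T @ da
            grads["b1"] = da.sum(axis=0)

            step += 1
            for k in W:
                adam_m[k] = b1m * adam_m[k] + (1 - b1m) * grads[k]
                adam_v[k] = b2m * adam_v[k] + (1 - b2m) * grads[k] ** 2
                mhat = adam_m[k] / (1 - b1m ** step)
                vhat = adam_v[k] / (1 - b2m ** step)
                W[k] -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
        loss = epoch_loss / n_tr

    for k in W:
        head[k] = W[k].astype(np.float64)
    if cfg.head == "regress":
        head["y_mu"], head["y_sd"] = y_mu, y_sd

    zs_ev = (z_ev - mu) / sd
    out = np.maximum(zs_ev @ W["W1"] + W["b1"], 0.0) @ W["W2"] + W["b2"]
    if cfg.head == "classify":
        pred = out.argmax(axis=1) + 1
        metric = float(np.mean(pred == y_ev.astype(int)))
        metric_name = "accuracy"
    else:
        pred_ev = out[:, 0] * y_sd + y_mu
        metric = float(np.sqrt(np.mean((pred_ev - y_ev) ** 2)))
        metric_name = "rmse"

    return TrainReport(
        final_train_loss=loss,
        eval_metric=metric,
        metric_name=metric_name,
        epochs=cfg.epochs,
        seed=cfg.seed,
        params=params,
    )
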