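"""GINet: a two-branch graph interaction network for interface graphs.

The graph is split into two sub-graphs sharing the node set: one carrying
the internal edges (contacts within a chain) and one the external edges
(contacts across the interface).  Each branch applies two rounds of
edge-strength-weighted message passing

    h'_i = ReLU( W_self h_i + b + sum_{j in N(i)} e_ij W_nbr h_j )

over its own edge set, then pools node embeddings by a per-feature mean.
The two pooled vectors are concatenated and passed through two fully
connected layers.  The forward pass depends only on node features and
edge weights, so the output is invariant to node reordering (after
pooling) and to rigid transforms of the original coordinates (which the
upstream features never see).

The network, its analytic gradients and the Adam optimizer are
implemented directly on NumPy arrays; gradients are validated against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .graph import InterfaceGraph


@dataclass
class GINetConfig:
    """Architecture hyperparameters.

    n_features : input node-feature width F
    hidden     : width of each convolution layer (default 16)
    n_conv     : convolution blocks per branch (default 2)
    fc_hidden  : width of the first fully connected layer (default 128)
    task       : "regression" (scalar output) or "classification"
    n_classes  : output dimension for classification
    """

    n_features: int
    hidden: int = 16
    n_conv: int = 2
    fc_hidden: int = 128
    task: str = "regression"
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if min(self.n_features, self.hidden, self.n_conv, self.fc_hidden) < 1:
            raise ValueError("all widths must be positive")

    @property
    def out_dim(self) -> int:
        return 1 if self.task == "regression" else self.n_classes


@dataclass
class TrainConfig:
    """Optimization settings (Adam; MSE for regression, cross-entropy with
    optional inverse-frequency class weights for classification)."""

    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 0.001
    seed: int = 0
    class_weights: dict | None = None   # class -> weight; None = uniform
    auto_class_weights: bool = False    # derive weights from training labels
    scale_features: bool = True         # min-max scale columns on the train set

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("invalid training configuration")


# --- data preparation -------------------------------------------------------

@dataclass
class GraphSample:
    """Dense per-graph tensors consumed by the network."""

    id: str
    x: np.ndarray        # (N, F) node features
    adj_int: np.ndarray  # (N, N) symmetric edge-strength adjacency
    adj_ext: np.ndarray  # (N, N)
    target: float | int | None = None


def _dense_adjacency(n: int, edges: np.ndarray, weights: np.ndarray) -> np.ndarray:
    adj = np.zeros((n, n))
    for (i, j), w in zip(edges, weights):
        adj[i, j] = w
        adj[j, i] = w
    return adj


def to_sample(graph: InterfaceGraph, target=None) -> GraphSample:
    """Convert a featurized InterfaceGraph into dense training tensors."""
    if graph.node_features is None:
        raise ValueError(f"graph {graph.id}: features not filled")
    if graph.internal_edge_feat is None or graph.external_edge_feat is None:
        raise ValueError(f"graph {graph.id}: edge features not filled")
    n = graph.n_nodes
    return GraphSample(
        id=graph.id,
        x=np.asarray(graph.node_features, dtype=float),
        adj_int=_dense_adjacency(n, graph.internal_edges, graph.internal_edge_feat),
        adj_ext=_dense_adjacency(n, graph.external_edges, graph.external_edge_feat),
        target=target,
    )


# --- the model --------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GINetModel:
    """Two-branch message-passing network over interface graphs."""

    def __init__(self, config: GINetConfig, seed: int = 0,
                 feature_names: list[str] | None = None):
        self.config = config
        self.feature_names = list(feature_names or [])
        self.scaler: tuple[np.ndarray, np.ndarray] | None = None  # (min, range)
        rng = np.random.default_rng(seed)
        F, H = config.n_features, config.hidden
        self.params: dict[str, np.ndarray] = {}
        for branch in ("int", "ext"):
            for layer in range(config.n_conv):
                fin = F if layer == 0 else H
                self.params[f"{branch}_W_self{layer}"] = _glorot(rng, fin, H)
                self.params[f"{branch}_W_nbr{layer}"] = _glorot(rng, fin, H)
                self.params[f"{branch}_b{layer}"] = np.zeros(H)
        self.params["fc1_W"] = _glorot(rng, 2 * H, config.fc_hidden)
        self.params["fc1_b"] = np.zeros(config.fc_hidden)
        self.params["fc2_W"] = _glorot(rng, config.fc_hidden, config.out_dim)
        self.params["fc2_b"] = np.zeros(config.out_dim)

    # -- scaling --

    def fit_scaler(self, samples: list[GraphSample]) -> None:
        stacked = np.vstack([s.x for s in samples])
        lo = stacked.min(axis=0)
        rng_ = stacked.max(axis=0) - lo
        rng_[rng_ == 0] = 1.0
        self.scaler = (lo, rng_)

    def _scale(self, x: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            return x
        lo, rng_ = self.scaler
        return (x - lo) / rng_

    # -- forward / backward --

    def forward(self, sample: GraphSample, cache: dict | None = None) -> np.ndarray:
        """Network output for one graph: shape (1,) or (n_classes,)."""
        if sample.x.shape[1] != self.config.n_features:
            raise ValueError(
                f"graph {sample.id}: feature width {sample.x.shape[1]} does not "
                f"match model width {self.config.n_features}")
        x0 = self._scale(sample.x)
        pooled = []
        for branch, adj in (("int", sample.adj_int), ("ext", sample.adj_ext)):
            h = x0
            for layer in range(self.config.n_conv):
                z = (h @ self.params[f"{branch}_W_self{layer}"]
                     + (adj @ h) @ self.params[f"{branch}_W_nbr{layer}"]
                     + self.params[f"{branch}_b{layer}"])
                h_new = np.maximum(z, 0.0)
                if cache is not None:
                    cache[f"{branch}_h{layer}"] = h
                    cache[f"{branch}_z{layer}"] = z
                h = h_new
            pooled.append(h.mean(axis=0))
            if cache is not None:
                cache[f"{branch}_n"] = h.shape[0]
        zcat = np.concatenate(pooled)
        a1 = zcat @ self.params["fc1_W"] + self.params["fc1_b"]
        h1 = np.maximum(a1, 0.0)
        out = h1 @ self.params["fc2_W"] + self.params["fc2_b"]
        if cache is not None:
            cache["zcat"], cache["a1"], cache["h1"] = zcat, a1, h1
            cache["x0"], cache["adj"] = x0, {"int": sample.adj_int, "ext": sample.adj_ext}
        return out

    def backward(self, cache: dict, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the per-sample loss w.r.t. every parameter."""
        g = {k: np.zeros_like(v) for k, v in self.params.items()}
        g["fc2_W"] = np.outer(cache["h1"], dout)
        g["fc2_b"] = dout.copy()
        dh1 = self.params["fc2_W"] @ dout
        da1 = dh1 * (cache["a1"] > 0)
        g["fc1_W"] = np.outer(cache["zcat"], da1)
        g["fc1_b"] = da1.copy()
        dzcat = self.params["fc1_W"] @ da1
        H = self.config.hidden
        for bi, branch in enumerate(("int", "ext")):
            adj = cache["adj"][branch]
            n = cache[f"{branch}_n"]
            dpool = dzcat[bi * H:(bi + 1) * H]
            dh = np.tile(dpool / n, (n, 1))  # mean-pool gradient
            for layer in reversed(range(self.config.n_conv)):
                dz = dh * (cache[f"{branch}_z{layer}"] > 0)
                h_in = cache[f"{branch}_h{layer}"]
                ah = adj @ h_in
                g[f"{branch}_W_self{layer}"] = h_in.T @ dz
                g[f"{branch}_W_nbr{layer}"] = ah.T @ dz
                g[f"{branch}_b{layer}"] = dz.sum(axis=0)
                if layer > 0:
                    dh = (dz @ self.params[f"{branch}_W_self{layer}"].T
                          + adj.T @ (dz @ self.params[f"{branch}_W_nbr{layer}"].T))
        return g

    # -- losses --

    def loss_and_grad(self, sample: GraphSample, weights: dict | None = None):
        """(loss, dloss/dout, output) for one sample under the task loss."""
        cache: dict = {}
        out = self.forward(sample, cache)
        y = sample.target
        if self.config.task == "regression":
            err = out[0] - float(y)
            return err * err, np.array([2.0 * err]), out, cache
        # weighted softmax cross-entropy
        logits = out - out.max()
        p = np.exp(logits)
        p /= p.sum()
        yi = int(y)
        w = 1.0 if weights is None else float(weights.get(yi, 1.0))
        loss = -w * np.log(max(p[yi], 1e-300))
        dout = w * p.copy()
        dout[yi] -= w
        return loss, dout, out, cache

    # -- persistence --

    def save(self, path: str | Path) -> None:
        """Serialize parameters, config, scaler and feature names as JSON."""
        blob = {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "scaler": None if self.scaler is None else
                      [self.scaler[0].tolist(), self.scaler[1].tolist()],
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "GINetModel":
        blob = json.loads(Path(path).read_text())
        model = cls(GINetConfig(**blob["config"]), feature_names=blob["feature_names"])
        model.params = {k: np.array(v, dtype=float) for k, v in blob["params"].items()}
        if blob["scaler"] is not None:
            model.scaler = (np.array(blob["scaler"][0]), np.array(blob["scaler"][1]))
        return model


# --- training ---------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    model: "GINetModel"
    train_loss: list[float] = field(default_factory=list)
    eval_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def evaluate_loss(model: GINetModel, samples: list[GraphSample],
                  weights: dict | None = None) -> float:
    total = 0.0
    for s in samples:
        loss, *_ = model.loss_and_grad(s, weights)
        total += float(loss)
    return total / len(samples)


def train(model: GINetModel, train_set: list[GraphSample],
          eval_set: list[GraphSample], config: TrainConfig) -> TrainResult:
    """Mini-batch Adam training with per-epoch shuffling.

    The returned model carries the parameters that achieved the minimum
    evaluation-set loss across epochs; the full per-epoch loss traces are
    reported alongside.
    """
    if not train_set or not eval_set:
        raise ValueError("training and evaluation sets must be non-empty")
    widths = {s.x.shape[1] for s in train_set + eval_set}
    if widths != {model.config.n_features}:
        raise ValueError(f"feature widths {widths} do not match model "
                         f"({model.config.n_features})")

    weights = config.class_weights
    if model.config.task == "classification" and config.auto_class_weights:
        from .targets import class_weights as auto_weights
        weights = auto_weights([int(s.target) for s in train_set])

    if config.scale_features:
        model.fit_scaler(train_set)

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.params, config.learning_rate)
    result = TrainResult(model=model)
    best_loss, best_params = np.inf, None

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            for s in batch:
                loss, dout, _, cache = model.loss_and_grad(s, weights)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, graph {s.id}")
                epoch_loss += float(loss)
                for k, gv in model.backward(cache, dout).items():
                    grads[k] += gv
            for k in grads:
                grads[k] /= len(batch)
            opt.step(model.params, grads)
        result.train_loss.append(epoch_loss / len(train_set))
        ev = evaluate_loss(model, eval_set, weights)
        result.eval_loss.append(ev)
        if ev < best_loss:
            best_loss = ev
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
    model.params = best_params
    result.best_epoch = best_epoch
    return result


def predict(model: GINetModel, samples: list[GraphSample]) -> np.ndarray:
    """Scores (regression, shape (n,)) or class probabilities (n, C)."""
    if not samples:
        return (np.zeros(0) if model.config.task == "regression"
                else np.zeros((0, model.config.out_dim)))
    outs = np.array([model.forward(s) for s in samples])
    if model.config.task == "regression":
        return outs[:, 0]
    logits = outs - outs.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)
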