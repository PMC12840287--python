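"""Hybrid GCN + soft decision tree regressor for RMST pseudo-values.

Two graph-convolution layers H^(v+1) = ReLU(A_hat H^(v) W^(v)) embed each
subject using its graph neighborhood; the embedding is mapped by one shared
affine layer to a scalar f_e per internal tree node, the sigmoid d_e = s(f_e)
soft-routes the subject left (probability d_e) or right (1 - d_e), and the
prediction at horizon tau_k is the routing-probability-weighted mean of the
leaf values lambda_lk:

    g(X_i, tau_k) = sum_l lambda_lk * p_l(X_i),   p_l = prod over the path.

Training minimizes the pseudo-value mean squared error
L = 1/(nK) sum_ik (y~_ik - g_ik)^2 with full-batch Adam over the whole graph
(transductive: propagation sees every node, the loss is masked to training
nodes).  All gradients are hand-derived backprop through this exact forward
pass; closed-form per-node expressions (decision_node_gradient,
leaf_gradient) are kept as separately testable quantities.

Trees are stored in heap order: node 0 is the root, node e has children
2e+1 (left) and 2e+2 (right); internal nodes are 0 .. 2^depth-2 and the
2^depth leaves are heap indices 2^depth-1 .. 2^(depth+1)-2.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GCNParams:
    W0: np.ndarray  # (p, h1)
    W1: np.ndarray  # (h1, h2)
    dropout_rate: float = 0.1


@dataclass
class TreeParams:
    depth: int
    Wt: np.ndarray      # (h2, n_internal) shared affine map to node scores
    bt: np.ndarray      # (n_internal,)
    leaves: np.ndarray  # (n_leaves, K) per-leaf RMST vectors lambda_lk

    @property
    def n_internal(self) -> int:
        return 2 ** self.depth - 1

    @property
    def n_leaves(self) -> int:
        return 2 ** self.depth


@dataclass
class GTModel:
    gcn: GCNParams
    tree: TreeParams
    taus: np.ndarray
    kn: int | None = None

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        return {"W0": self.gcn.W0, "W1": self.gcn.W1,
                "Wt": self.tree.Wt, "bt": self.tree.bt,
                "leaves": self.tree.leaves}

    def save(self, path) -> None:
        """Serialize weights + topology + config to a single zip archive."""
        meta = {"depth": self.tree.depth, "kn": self.kn,
                "dropout_rate": self.gcn.dropout_rate,
                "taus": np.asarray(self.taus, float).tolist()}
        buf = io.BytesIO()
        np.savez(buf, **self.parameters)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "GTModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrs = np.load(io.BytesIO(zf.read("weights.npz")))
            gcn = GCNParams(W0=arrs["W0"], W1=arrs["W1"],
                            dropout_rate=meta["dropout_rate"])
            tree = TreeParams(depth=meta["depth"], Wt=arrs["Wt"],
                              bt=arrs["bt"], leaves=arrs["leaves"])
        return cls(gcn=gcn, tree=tree, taus=np.asarray(meta["taus"]),
                   kn=meta["kn"])


def init_model(
    p: int,
    hidden: tuple[int, int],
    depth: int,
    taus: np.ndarray,
    rng: np.random.Generator,
    leaf_init: np.ndarray | None = None,
    dropout_rate: float = 0.1,
    kn: int | None = None,
) -> GTModel:
    """Glorot-uniform GCN and routing weights; leaves at the per-horizon
    mean target (``leaf_init``) plus small noise, or zero."""
    h1, h2 = hidden
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    K = taus.shape[0]
    n_internal = 2 ** depth - 1
    n_leaves = 2 ** depth

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    base = np.zeros(K) if leaf_init is None else np.asarray(leaf_init, float)
    leaves = base[None, :] + 0.01 * rng.standard_normal((n_leaves, K))
    gcn = GCNParams(W0=glorot(p, h1), W1=glorot(h1, h2),
                    dropout_rate=dropout_rate)
    tree = TreeParams(depth=depth, Wt=glorot(h2, n_internal),
                      bt=np.zeros(n_internal), leaves=leaves)
    return GTModel(gcn=gcn, tree=tree, taus=taus, kn=kn)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

@dataclass
class ForwardCache:
    """Intermediate tensors of one forward pass, consumed by backprop."""

    X: np.ndarray
    A_hat: np.ndarray
    Z1: np.ndarray
    H1d: np.ndarray      # post-ReLU post-dropout layer-1 output
    Z2: np.ndarray
    H2d: np.ndarray      # tree input
    M1: np.ndarray | None
    M2: np.ndarray | None
    F: np.ndarray        # (n, n_internal) node scores
    d: np.ndarray        # sigmoid(F): probability of routing LEFT
    node_probs: np.ndarray  # (n, 2^(depth+1)-1) reach probability per heap node
    P: np.ndarray        # (n, n_leaves) leaf routing probabilities
    G: np.ndarray        # (n, K) predictions


def gcn_forward(X, A_hat, params: GCNParams, training: bool = False,
                rng: np.random.Generator | None = None):
    """Two propagate-transform-ReLU layers with inverted dropout after each
    ReLU (training only).  Returns (output, cache-pieces)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.W0.shape[0]:
        raise ValueError(f"X has {X.shape[1]} features, W0 expects "
                         f"{params.W0.shape[0]}")
    if A_hat.shape[0] != X.shape[0]:
        raise ValueError("A_hat and X disagree on the number of nodes")
    q = params.dropout_rate
    Z1 = A_hat @ X @ params.W0
    H1 = relu(Z1)
    M1 = M2 = None
    if training and q > 0:
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        M1 = (rng.random(H1.shape) >= q).astype(float)
        H1 = H1 * M1 / (1.0 - q)
    Z2 = A_hat @ H1 @ params.W1
    H2 = relu(Z2)
    if training and q > 0:
        M2 = (rng.random(H2.shape) >= q).astype(float)
        H2 = H2 * M2 / (1.0 - q)
    return Z1, H1, Z2, H2, M1, M2


def routing_probs(H: np.ndarray, tree: TreeParams):
    """Leaf routing probabilities; rows are probability vectors.

    Returns (F, d, node_probs, P): node scores, left-routing sigmoids,
    per-heap-node reach probabilities, and the (n, n_leaves) leaf matrix.
    """
    F = H @ tree.Wt + tree.bt
    d = sigmoid(F)
    n = H.shape[0]
    total = 2 ** (tree.depth + 1) - 1
    node_probs = np.empty((n, total))
    node_probs[:, 0] = 1.0
    for e in range(tree.n_internal):
        node_probs[:, 2 * e + 1] = node_probs[:, e] * d[:, e]
        node_probs[:, 2 * e + 2] = node_probs[:, e] * (1.0 - d[:, e])
    P = node_probs[:, tree.n_internal:]
    return F, d, node_probs, P


def forward(X, A_hat, model: GTModel, training: bool = False,
            rng: np.random.Generator | None = None) -> ForwardCache:
    Z1, H1d, Z2, H2d, M1, M2 = gcn_forward(X, A_hat, model.gcn,
                                           training=training, rng=rng)
    F, d, node_probs, P = routing_probs(H2d, model.tree)
    G = P @ model.tree.leaves
    return ForwardCache(X=np.asarray(X, float), A_hat=np.asarray(A_hat, float),
                        Z1=Z1, H1d=H1d, Z2=Z2, H2d=H2d, M1=M1, M2=M2,
                        F=F, d=d, node_probs=node_probs, P=P, G=G)


def predict_rmst(X, A_hat, model) -> np.ndarray:
    """Deterministic n×K RMST predictions (no dropout).  For the tree head
    each entry is a convex combination of the leaf values at that horizon."""
    if isinstance(model, GTModel):
        return forward(X, A_hat, model, training=False).G
    return forward_linear(X, A_hat, model, training=False).G


def loss(pred: np.ndarray, target: np.ndarray,
         mask: np.ndarray | None = None) -> float:
    """Pseudo-value MSE 1/(nK) sum_ik (y~_ik - g_ik)^2, optionally restricted
    to the subjects selected by ``mask``."""
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    if mask is not None:
        pred, target = pred[mask], target[mask]
    return float(np.mean((target - pred) ** 2))


# ---------------------------------------------------------------------------
# backprop
# ---------------------------------------------------------------------------

def backward(cache: ForwardCache, model: GTModel, target: np.ndarray,
             mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Exact gradients of the masked pseudo-value MSE w.r.t. all parameters."""
    n, K = cache.G.shape
    tree = model.tree
    dG = np.zeros_like(cache.G)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    n_mask = int(mask.sum())
    dG[mask] = 2.0 / (n_mask * K) * (cache.G[mask] - target[mask])

    grads: dict[str, np.ndarray] = {}
    grads["leaves"] = cache.P.T @ dG

    # backprop through the reach-probability recursion
    total = 2 ** (tree.depth + 1) - 1
    dnode = np.zeros((n, total))
    dnode[:, tree.n_internal:] = dG @ tree.leaves.T
    dF = np.empty_like(cache.F)
    for e in range(tree.n_internal - 1, -1, -1):
        l, r = 2 * e + 1, 2 * e + 2
        dF[:, e] = (cache.node_probs[:, e]
                    * (dnode[:, l] - dnode[:, r])
                    * cache.d[:, e] * (1.0 - cache.d[:, e]))
        dnode[:, e] = cache.d[:, e] * dnode[:, l] \
            + (1.0 - cache.d[:, e]) * dnode[:, r]

    grads["Wt"] = cache.H2d.T @ dF
    grads["bt"] = dF.sum(axis=0)
    dH2d = dF @ tree.Wt.T

    q = model.gcn.dropout_rate
    dH2 = dH2d if cache.M2 is None else dH2d * cache.M2 / (1.0 - q)
    dZ2 = dH2 * (cache.Z2 > 0)
    grads["W1"] = (cache.A_hat @ cache.H1d).T @ dZ2
    dH1d = cache.A_hat.T @ dZ2 @ model.gcn.W1.T
    dH1 = dH1d if cache.M1 is None else dH1d * cache.M1 / (1.0 - q)
    dZ1 = dH1 * (cache.Z1 > 0)
    grads["W0"] = (cache.A_hat @ cache.X).T @ dZ1
    return grads


# ---------------------------------------------------------------------------
# closed-form per-node gradients (verification quantities)
# ---------------------------------------------------------------------------

def subtree_outputs(cache: ForwardCache, tree: TreeParams) -> np.ndarray:
    """Soft prediction A_e(k) of every heap node's own subtree, bottom-up:
    a leaf predicts its lambda vector, an internal node the d_e-weighted mix
    of its children.  Shape (n, total_nodes, K); the root slice equals G."""
    n, K = cache.G.shape
    total = 2 ** (tree.depth + 1) - 1
    A = np.empty((n, total, K))
    A[:, tree.n_internal:, :] = tree.leaves[None, :, :]
    for e in range(tree.n_internal - 1, -1, -1):
        de = cache.d[:, e, None]
        A[:, e] = de * A[:, 2 * e + 1] + (1.0 - de) * A[:, 2 * e + 2]
    return A


def decision_node_gradient(cache: ForwardCache, tree: TreeParams,
                           target: np.ndarray) -> np.ndarray:
    """Per-sample, per-node dL/df_e in closed form.

    dL/df_e(X_i) = 2/(nK) * P(reach e) * d_e * (1-d_e)
                   * sum_k r_ik (A_el(k) - A_er(k)),
    with r_ik = g_ik - y~_ik, d_e the left-routing probability, and A_el /
    A_er the left / right subtree outputs.  The reach probability (prefix
    product over the node's ancestors) is required for this to be the true
    gradient of the loss — verified against finite differences in the tests.
    Saturated nodes (d_e in {0,1}) and nodes whose subtrees agree get zero.
    """
    n, K = cache.G.shape
    r = cache.G - target
    A = subtree_outputs(cache, tree)
    out = np.empty((n, tree.n_internal))
    for e in range(tree.n_internal):
        diff = A[:, 2 * e + 1] - A[:, 2 * e + 2]  # A_el - A_er
        out[:, e] = (2.0 / (n * K)
                     * cache.node_probs[:, e]
                     * cache.d[:, e] * (1.0 - cache.d[:, e])
                     * np.sum(r * diff, axis=1))
    return out


def leaf_gradient(cache: ForwardCache, tree: TreeParams,
                  target: np.ndarray) -> np.ndarray:
    """Closed-form dL/dlambda_lk = 2/(nK) sum_i (g_ik - y~_ik) p_l(X_i)."""
    n, K = cache.G.shape
    return 2.0 / (n * K) * cache.P.T @ (cache.G - target)


# ---------------------------------------------------------------------------
# linear-head variant (GCN-only and fully-connected baselines)
# ---------------------------------------------------------------------------

@dataclass
class LinearHeadModel:
    """Two propagation layers + a linear K-output head (no decision tree).

    With the graph's normalized adjacency this is the GCN-only ablation;
    with the identity adjacency the propagation reduces to plain
    fully-connected layers (the DNN baseline).
    """

    gcn: GCNParams
    Wh: np.ndarray  # (h2, K)
    bh: np.ndarray  # (K,)
    taus: np.ndarray | None = None

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        return {"W0": self.gcn.W0, "W1": self.gcn.W1,
                "Wh": self.Wh, "bh": self.bh}


@dataclass
class LinearForwardCache:
    X: np.ndarray
    A_hat: np.ndarray
    Z1: np.ndarray
    H1d: np.ndarray
    Z2: np.ndarray
    H2d: np.ndarray
    M1: np.ndarray | None
    M2: np.ndarray | None
    G: np.ndarray


def init_linear_model(p, hidden, K, rng: np.random.Generator,
                      head_init=None, dropout_rate=0.1) -> LinearHeadModel:
    h1, h2 = hidden

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    bh = (np.zeros(K) if head_init is None
          else np.asarray(head_init, float).copy())
    gcn = GCNParams(W0=glorot(p, h1), W1=glorot(h1, h2),
                    dropout_rate=dropout_rate)
    return LinearHeadModel(gcn=gcn, Wh=glorot(h2, K), bh=bh)


def forward_linear(X, A_hat, model: LinearHeadModel, training=False,
                   rng=None) -> LinearForwardCache:
    Z1, H1d, Z2, H2d, M1, M2 = gcn_forward(X, A_hat, model.gcn,
                                           training=training, rng=rng)
    G = H2d @ model.Wh + model.bh
    return LinearForwardCache(X=np.asarray(X, float),
                              A_hat=np.asarray(A_hat, float),
                              Z1=Z1, H1d=H1d, Z2=Z2, H2d=H2d,
                              M1=M1, M2=M2, G=G)


def backward_linear(cache: LinearForwardCache, model: LinearHeadModel,
                    target, mask=None) -> dict[str, np.ndarray]:
    n, K = cache.G.shape
    dG = np.zeros_like(cache.G)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    n_mask = int(mask.sum())
    dG[mask] = 2.0 / (n_mask * K) * (cache.G[mask] - target[mask])
    grads = {"Wh": cache.H2d.T @ dG, "bh": dG.sum(axis=0)}
    dH2d = dG @ model.Wh.T
    q = model.gcn.dropout_rate
    dH2 = dH2d if cache.M2 is None else dH2d * cache.M2 / (1.0 - q)
    dZ2 = dH2 * (cache.Z2 > 0)
    grads["W1"] = (cache.A_hat @ cache.H1d).T @ dZ2
    dH1d = cache.A_hat.T @ dZ2 @ model.gcn.W1.T
    dH1 = dH1d if cache.M1 is None else dH1d * cache.M1 / (1.0 - q)
    dZ1 = dH1 * (cache.Z1 > 0)
    grads["W0"] = (cache.A_hat @ cache.X).T @ dZ1
    return grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    hidden: tuple[int, int] = (64, 32)
    depth: int = 3
    lr: float = 1e-3
    epochs: int = 1000
    dropout: float = 0.1
    weight_decay: float = 5e-4  # L2 on W0, W1, Wt (not leaves/bias)
    patience: int = 50
    seed: int = 0


@dataclass
class TrainResult:
    model: GTModel
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(X, A_hat, pseudo_values, train_idx, val_idx,
          config: TrainConfig, taus=None, kn: int | None = None,
          head: str = "tree") -> TrainResult:
    """Full-batch transductive training with Adam and early stopping.

    Every epoch runs one forward pass over the whole graph; the loss (and
    its gradient) is masked to ``train_idx``.  Validation MSE on ``val_idx``
    (dropout off) drives early stopping with best-weight restoration.
    Deterministic given the config seed.

    ``head`` selects the output module: "tree" (soft decision tree, the full
    model) or "linear" (linear K-output head, the GCN-only / DNN baselines —
    pass the identity for ``A_hat`` to turn propagation into plain FC layers).
    """
    X = np.asarray(X, float)
    Y = np.asarray(pseudo_values, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, K = Y.shape
    if taus is None:
        taus = np.arange(1, K + 1, dtype=float)
    rng = np.random.default_rng(config.seed)

    train_mask = np.zeros(n, dtype=bool)
    train_mask[np.asarray(train_idx)] = True
    val_mask = np.zeros(n, dtype=bool)
    val_mask[np.asarray(val_idx)] = True
    if not train_mask.any():
        raise ValueError("empty training index set")

    head_init = Y[train_mask].mean(axis=0)
    if head == "tree":
        model = init_model(p=X.shape[1], hidden=tuple(config.hidden),
                           depth=config.depth, taus=taus, rng=rng,
                           leaf_init=head_init, dropout_rate=config.dropout,
                           kn=kn)
        fwd, bwd = forward, backward
        decayed = ("W0", "W1", "Wt")
    elif head == "linear":
        model = init_linear_model(p=X.shape[1], hidden=tuple(config.hidden),
                                  K=K, rng=rng, head_init=head_init,
                                  dropout_rate=config.dropout)
        model.taus = np.atleast_1d(np.asarray(taus, float))
        fwd, bwd = forward_linear, backward_linear
        decayed = ("W0", "W1", "Wh")
    else:
        raise ValueError(f"unknown head {head!r}")
    params = model.parameters
    opt = _Adam(params, lr=config.lr)

    best_val = np.inf
    best_weights = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    since_best = 0
    hist_train, hist_val = [], []
    stopped = False

    for epoch in range(config.epochs):
        cache = fwd(X, A_hat, model, training=True, rng=rng)
        tr_loss = loss(cache.G, Y, mask=train_mask)
        if not np.isfinite(tr_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (loss={tr_loss}); "
                "inspect learning rate / weight decay")
        grads = bwd(cache, model, Y, mask=train_mask)
        for k in decayed:
            grads[k] = grads[k] + config.weight_decay * params[k]
        opt.step(params, grads)

        G_eval = fwd(X, A_hat, model, training=False).G
        hist_train.append(loss(G_eval, Y, mask=train_mask))
        if val_mask.any():
            vl = loss(G_eval, Y, mask=val_mask)
            hist_val.append(vl)
            if vl < best_val - 1e-12:
                best_val = vl
                best_weights = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    stopped = True
                    break

    if val_mask.any():
        for k, v in params.items():
            v[...] = best_weights[k]
    return TrainResult(model=model, train_loss=hist_train, val_loss=hist_val,
                       best_epoch=best_epoch, stopped_early=stopped)
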