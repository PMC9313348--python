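"""Multi-head graph attention + graph convolution link predictor.

The forward model, implemented directly in NumPy with hand-derived
reverse-mode gradients:

1. **GAT layer(s)**: per head ``h``, attention logits
   ``e_ij = LeakyReLU(a_h^T [W_h b_i || W_h b_j])`` over the neighborhood
   ``N(i)`` taken from the nonzeros of ``M + I`` (self-loops keep isolated
   nodes well-defined), softmax-normalized to ``alpha_ij``; the head output
   is ``sum_j alpha_ij W_h b_j`` and heads are averaged, then ReLU.
2. **GCN layer(s)**: ``ReLU(D^{-1/2} (M + I) D^{-1/2} H W)``.
3. **Pair scorer**: the concatenated embeddings ``[H_c || H_d]`` pass
   through a fully connected network with ReLU hidden layers whose widths
   halve per layer, ending in a sigmoid; alternatively (``use_fc=False``)
   the score is the sigmoid of the embedding inner product.

Training minimizes mean binary cross-entropy plus ``lambda_l2/2`` times the
squared norm of all parameters, with full-batch Adam. Everything is
deterministic given the config seed (single-platform bit reproducibility;
cross-platform float drift is tolerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

LEAKY_SLOPE = 0.2
_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; the defaults are the best-performing settings of
    the parameter analysis (16 heads, one GAT and one GCN layer, embedding
    width 256, a 3-layer predictor)."""

    n_heads: int = 16
    gat_layers: int = 1
    gcn_layers: int = 1
    embed_dim: int = 256
    fc_layers: int = 3
    lambda_l2: float = 1e-4
    lr: float = 0.005
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_heads", "gat_layers", "gcn_layers", "embed_dim", "fc_layers", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


class EdgeIndex(NamedTuple):
    """Directed edges of M + I grouped by aggregating (source) node."""

    src: np.ndarray
    dst: np.ndarray
    row_ptr: np.ndarray  # first edge index of each node's segment
    n: int


def build_edge_index(M: np.ndarray) -> EdgeIndex:
    n = M.shape[0]
    Mt = (np.asarray(M) != 0) | np.eye(n, dtype=bool)
    src, dst = np.nonzero(Mt)  # row-major: sorted by src
    row_ptr = np.searchsorted(src, np.arange(n))
    return EdgeIndex(src=src, dst=dst, row_ptr=row_ptr, n=n)


def normalized_adjacency(M: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation matrix ``D^{-1/2} (M + I) D^{-1/2}``."""
    Mt = np.asarray(M, dtype=float) + np.eye(M.shape[0])
    dinv = 1.0 / np.sqrt(Mt.sum(axis=1))
    return Mt * dinv[:, None] * dinv[None, :]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def bce_loss(
    scores: np.ndarray,
    labels: np.ndarray,
    params: list[np.ndarray] | None = None,
    lambda_l2: float = 0.0,
) -> float:
    """Mean binary cross-entropy with optional L2 penalty
    ``(lambda/2) * ||Theta||^2``; scores clamped to [eps, 1-eps]."""
    s = np.clip(np.asarray(scores, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    loss = -np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s))
    if params is not None and lambda_l2 > 0:
        loss += 0.5 * lambda_l2 * sum(float((p**2).sum()) for p in params)
    return float(loss)


class GatGcnModel:
    """The trainable predictor over a heterogeneous graph.

    Parameters are plain NumPy arrays in ``self.params``; the backward
    pass is derived by hand and validated against finite differences.
    Ablation switches drop the GAT stack, the GCN stack (at least one must
    remain), or replace the FC scorer with an inner product.
    """

    def __init__(
        self,
        n_input: int,
        cfg: ModelConfig = ModelConfig(),
        use_gat: bool = True,
        use_gcn: bool = True,
        use_fc: bool = True,
    ) -> None:
        if not (use_gat or use_gcn):
            raise ValueError("at least one of GAT/GCN must be enabled")
        self.cfg = cfg
        self.n_input = n_input
        self.use_gat, self.use_gcn, self.use_fc = use_gat, use_gcn, use_fc
        rng = np.random.default_rng(cfg.seed)
        d = cfg.embed_dim
        self.params: dict[str, np.ndarray] = {}

        if use_gat:
            din = n_input
            for layer in range(cfg.gat_layers):
                self.params[f"gat{layer}.W"] = _glorot(rng, cfg.n_heads, din, d)
                self.params[f"gat{layer}.a_src"] = _glorot(rng, cfg.n_heads, d, 1)[..., 0]
                self.params[f"gat{layer}.a_dst"] = _glorot(rng, cfg.n_heads, d, 1)[..., 0]
                din = d
        if use_gcn:
            din = d if use_gat else n_input
            for layer in range(cfg.gcn_layers):
                self.params[f"gcn{layer}.W"] = _glorot(rng, din, d)
                din = d
        if use_fc:
            dims = [2 * d]
            for _ in range(cfg.fc_layers - 1):
                dims.append(max(dims[-1] // 2, 1))
            dims.append(1)
            for k in range(cfg.fc_layers):
                self.params[f"fc{k}.W"] = _glorot(rng, dims[k], dims[k + 1])
                self.params[f"fc{k}.b"] = np.zeros(dims[k + 1])
        self.loss_history: list[float] = []

    # ------------------------------------------------------------------ GAT

    def _gat_forward(self, B_in: np.ndarray, layer: int, edges: EdgeIndex):
        W = self.params[f"gat{layer}.W"]  # (H, din, d)
        a_src = self.params[f"gat{layer}.a_src"]  # (H, d)
        a_dst = self.params[f"gat{layer}.a_dst"]
        H, din, d = W.shape
        n = edges.n
        Z = (B_in @ W.transpose(1, 0, 2).reshape(din, H * d)).reshape(n, H, d)
        Z = np.ascontiguousarray(Z.transpose(1, 0, 2))  # (H, n, d)
        s = np.einsum("hnd,hd->hn", Z, a_src)
        t = np.einsum("hnd,hd->hn", Z, a_dst)
        logits = s[:, edges.src] + t[:, edges.dst]  # (H, E)
        act = np.where(logits > 0, logits, LEAKY_SLOPE * logits)
        mx = np.maximum.reduceat(act, edges.row_ptr, axis=1)
        ex = np.exp(act - mx[:, edges.src])
        denom = np.add.reduceat(ex, edges.row_ptr, axis=1)
        alpha = ex / denom[:, edges.src]
        O = np.empty((H, n, d))
        for h in range(H):
            O[h] = np.add.reduceat(alpha[h][:, None] * Z[h, edges.dst], edges.row_ptr, axis=0)
        mean = O.mean(axis=0)
        out = _relu(mean)
        cache = (B_in, Z, logits, alpha, mean)
        return out, cache

    def _gat_backward(self, dOut: np.ndarray, cache, layer: int, edges: EdgeIndex, grads):
        B_in, Z, logits, alpha, mean = cache
        W = self.params[f"gat{layer}.W"]
        a_src = self.params[f"gat{layer}.a_src"]
        a_dst = self.params[f"gat{layer}.a_dst"]
        H, din, d = W.shape
        n = edges.n
        dmean = dOut * (mean > 0)
        dO = dmean / H  # same for every head (head averaging)

        dZ = np.zeros_like(Z)
        dalpha = np.empty_like(alpha)
        dO_src = dO[edges.src]  # (E, d)
        for h in range(H):
            Zd = Z[h, edges.dst]
            dalpha[h] = np.einsum("ed,ed->e", dO_src, Zd)
            np.add.at(dZ[h], edges.dst, alpha[h][:, None] * dO_src)

        w = alpha * dalpha
        segsum = np.add.reduceat(w, edges.row_ptr, axis=1)
        de = alpha * (dalpha - segsum[:, edges.src])
        dlog = de * np.where(logits > 0, 1.0, LEAKY_SLOPE)
        ds = np.add.reduceat(dlog, edges.row_ptr, axis=1)  # (H, n), grouped by src
        dt = np.empty((H, n))
        for h in range(H):
            dt[h] = np.bincount(edges.dst, weights=dlog[h], minlength=n)

        grads[f"gat{layer}.a_src"] = np.einsum("hn,hnd->hd", ds, Z)
        grads[f"gat{layer}.a_dst"] = np.einsum("hn,hnd->hd", dt, Z)
        dZ += ds[:, :, None] * a_src[:, None, :]
        dZ += dt[:, :, None] * a_dst[:, None, :]

        dZ2 = np.ascontiguousarray(dZ.transpose(1, 0, 2)).reshape(n, H * d)
        grads[f"gat{layer}.W"] = (B_in.T @ dZ2).reshape(din, H, d).transpose(1, 0, 2)
        dB_in = dZ2 @ W.transpose(1, 0, 2).reshape(din, H * d).T
        return dB_in

    # ------------------------------------------------------------------ GCN

    def _gcn_forward(self, H_in: np.ndarray, layer: int, Ahat: np.ndarray):
        W = self.params[f"gcn{layer}.W"]
        P = Ahat @ H_in
        pre = P @ W
        return _relu(pre), (H_in, P, pre)

    def _gcn_backward(self, dOut: np.ndarray, cache, layer: int, Ahat: np.ndarray, grads):
        H_in, P, pre = cache
        W = self.params[f"gcn{layer}.W"]
        dpre = dOut * (pre > 0)
        grads[f"gcn{layer}.W"] = P.T @ dpre
        return Ahat.T @ (dpre @ W.T)

    # ------------------------------------------------------------- embedding

    def node_embeddings(self, M: np.ndarray, X: np.ndarray, return_cache: bool = False):
        """Forward pass through the GAT and GCN stacks.

        ``M`` supplies both the attention neighborhoods and the GCN
        propagation matrix; ``X`` is the initial feature matrix.
        """
        edges = build_edge_index(M)
        Ahat = normalized_adjacency(M) if self.use_gcn else None
        caches = []
        B = np.asarray(X, dtype=float)
        if self.use_gat:
            for layer in range(self.cfg.gat_layers):
                B, cache = self._gat_forward(B, layer, edges)
                caches.append(("gat", layer, cache))
        if self.use_gcn:
            for layer in range(self.cfg.gcn_layers):
                B, cache = self._gcn_forward(B, layer, Ahat)
                caches.append(("gcn", layer, cache))
        if return_cache:
            return B, (edges, Ahat, caches)
        return B

    def _embeddings_backward(self, dH: np.ndarray, ctx, grads) -> None:
        edges, Ahat, caches = ctx
        for kind, layer, cache in reversed(caches):
            if kind == "gcn":
                dH = self._gcn_backward(dH, cache, layer, Ahat, grads)
            else:
                dH = self._gat_backward(dH, cache, layer, edges, grads)

    # --------------------------------------------------------------- scoring

    def _score_forward(self, Hn: np.ndarray, pairs: np.ndarray):
        """Logits for (circ_node, dis_node) index pairs (graph node ids)."""
        ci, dj = pairs[:, 0], pairs[:, 1]
        if self.use_fc:
            F = np.concatenate([Hn[ci], Hn[dj]], axis=1)
            caches = []
            for k in range(self.cfg.fc_layers):
                W, b = self.params[f"fc{k}.W"], self.params[f"fc{k}.b"]
                pre = F @ W + b
                caches.append((F, pre))
                F = _relu(pre) if k < self.cfg.fc_layers - 1 else pre
            return F[:, 0], caches
        logits = np.einsum("ed,ed->e", Hn[ci], Hn[dj])
        return logits, Hn

    def _score_backward(self, dlogits: np.ndarray, cache, Hn, pairs, grads) -> np.ndarray:
        ci, dj = pairs[:, 0], pairs[:, 1]
        dH = np.zeros_like(Hn)
        if self.use_fc:
            dF = dlogits[:, None]
            for k in reversed(range(self.cfg.fc_layers)):
                F, pre = cache[k]
                # last layer is linear (sigmoid handled in the loss); hidden
                # layers pass through the ReLU mask
                dpre = dF if k == self.cfg.fc_layers - 1 else dF * (pre > 0)
                grads[f"fc{k}.W"] = F.T @ dpre
                grads[f"fc{k}.b"] = dpre.sum(axis=0)
                dF = dpre @ self.params[f"fc{k}.W"].T
            d = dF.shape[1] // 2
            np.add.at(dH, ci, dF[:, :d])
            np.add.at(dH, dj, dF[:, d:])
        else:
            np.add.at(dH, ci, dlogits[:, None] * Hn[dj])
            np.add.at(dH, dj, dlogits[:, None] * Hn[ci])
        return dH

    # ------------------------------------------------------------- training

    def loss_and_grads(self, M, X, pairs: np.ndarray, labels: np.ndarray):
        """Full-model loss (BCE + L2) and gradients for every parameter."""
        pairs = np.asarray(pairs)
        y = np.asarray(labels, dtype=float)
        Hn, ctx = self.node_embeddings(M, X, return_cache=True)
        logits, scache = self._score_forward(Hn, pairs)
        s = _sigmoid(logits)
        sc = np.clip(s, _EPS, 1.0 - _EPS)
        loss = -np.mean(y * np.log(sc) + (1.0 - y) * np.log(1.0 - sc))
        loss += 0.5 * self.cfg.lambda_l2 * sum(float((p**2).sum()) for p in self.params.values())

        grads: dict[str, np.ndarray] = {}
        dlogits = (s - y) / len(y)
        dH = self._score_backward(dlogits, scache, Hn, pairs, grads)
        self._embeddings_backward(dH, ctx, grads)
        for name, p in self.params.items():
            g = grads.get(name)
            grads[name] = self.cfg.lambda_l2 * p if g is None else g + self.cfg.lambda_l2 * p
        return float(loss), grads

    def fit(self, M, X, pos_pairs, neg_pairs) -> "GatGcnModel":
        """Full-batch Adam on balanced positive/negative node-index pairs.

        ``pos_pairs``/``neg_pairs`` are (circ_node, dis_node) graph-index
        pairs; diverging (NaN) loss aborts with a diagnostic.
        """
        pos = np.asarray(pos_pairs)
        neg = np.asarray(neg_pairs)
        if len(pos) != len(neg):
            raise ValueError("negative sample count must equal positive count")
        pairs = np.concatenate([pos, neg], axis=0)
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.loss_history = []
        for step in range(1, self.cfg.epochs + 1):
            loss, grads = self.loss_and_grads(M, X, pairs, labels)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {step}: loss={loss}")
            self.loss_history.append(loss)
            for k, p in self.params.items():
                g = grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mh = m[k] / (1 - b1**step)
                vh = v[k] / (1 - b2**step)
                p -= self.cfg.lr * mh / (np.sqrt(vh) + eps)
        return self

    def predict(self, M, X, pairs) -> np.ndarray:
        """Association probabilities for (circ_node, dis_node) pairs."""
        Hn = self.node_embeddings(M, X)
        logits, _ = self._score_forward(Hn, np.asarray(pairs))
        return _sigmoid(logits)
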