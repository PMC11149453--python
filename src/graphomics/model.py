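"""Sampled, attention-weighted graph neural network over the knowledge graph.

The model follows the GraphSAGE recipe: each node starts from a random
d-dimensional embedding (d = 100 by default; fixed input features unless
``train_embeddings`` is on) and is updated by aggregating a sampled,
fixed-size neighborhood over a fixed number of hops (two by default).
Messages along patient--feature edges are scaled by the edge weight (the
patient's normalized expression of that feature); feature--feature
messages carry weight 1.  Neighbor importance is
either uniform, ``alpha_uv = 1/|N(u)|`` over the aggregation set, or a
learned GAT-style additive score with per-edge-type parameters, softmax
normalized per destination.  A softmax layer on the final patient
embeddings classifies etiology, and the whole stack is trained end-to-end
with cross-entropy loss and Adam.

Everything is plain NumPy: forward, analytic backward and the Adam step are
implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import InputError, NumericError
from .graph import HeteroGraph

_LEAKY_SLOPE = 0.2
SELF_EDGE_TYPE = "self"


def _att3d(a: "np.ndarray") -> "np.ndarray":
    """Canonicalize attention score vectors to (n_heads, n_edge_types, d)."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        return a[None, None, :]
    if a.ndim == 2:
        return a[None, :, :]
    return a


# ---------------------------------------------------------------------------
# small numerics

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _relu_grad(pre: np.ndarray) -> np.ndarray:
    return (pre > 0).astype(pre.dtype)


_ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "identity": (lambda x: x, lambda pre: np.ones_like(pre)),
}


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# domain types

@dataclass
class EmbeddingSet:
    """Per-node d-dimensional vectors at message-passing layer ``layer_index``."""

    vectors: np.ndarray
    d: int
    layer_index: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != self.d:
            raise InputError(f"embedding matrix must be (n, {self.d})")
        if not np.all(np.isfinite(self.vectors)):
            raise NumericError("non-finite embedding entries")


@dataclass
class LayerParams:
    """One hop's weights: linear map W, activation tag, attention score vectors.

    ``att_dst`` / ``att_src`` may be 1-D (shared across edge types), 2-D
    (one row per edge type, in the graph's canonical edge-type order with a
    trailing ``self`` type), or 3-D with a leading head axis for the
    multi-head variant; ``None`` for the uniform-attention model.
    """

    W: np.ndarray
    activation: str = "relu"
    att_dst: np.ndarray | None = None
    att_src: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.activation not in _ACTIVATIONS:
            raise InputError(f"unknown activation {self.activation!r}")
        if not np.all(np.isfinite(self.W)):
            raise NumericError("non-finite weight matrix")


@dataclass
class AttentionMatrix:
    """Directed attention weights alpha_uv for messages v -> u.

    ``dst``/``src`` are node indices, ``alpha`` the weights; per destination
    the weights over its aggregation set (sampled neighbors, plus self when
    self loops are on) sum to one.
    """

    dst: np.ndarray
    src: np.ndarray
    alpha: np.ndarray
    n_nodes: int

    def row(self, u: int) -> dict[int, float]:
        mask = self.dst == u
        return dict(zip(self.src[mask].tolist(), self.alpha[mask].tolist()))

    def row_sums(self) -> np.ndarray:
        """Sum of weights per destination that has at least one message."""
        sums = np.bincount(self.dst, weights=self.alpha, minlength=self.n_nodes)
        present = np.bincount(self.dst, minlength=self.n_nodes) > 0
        return sums[present]

    def directed(self) -> dict[tuple[int, int], float]:
        """(u, v) -> alpha_uv lookup, self entries excluded."""
        keep = self.dst != self.src
        return {(int(u), int(v)): float(a)
                for u, v, a in zip(self.dst[keep], self.src[keep], self.alpha[keep])}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dst": self.dst, "src": self.src, "alpha": self.alpha})


@dataclass
class TrainConfig:
    """End-to-end training settings.

    ``neighbors_per_hop`` caps the sampled aggregation set per hop (an int
    applies to every hop); sampling is exhaustive, hence deterministic, when
    the cap reaches the maximum degree.  ``attention_mode`` is ``"uniform"``
    (alpha = 1/|N(u)|) or ``"learned"`` (GAT-style additive scores, with
    ``attention_heads`` softmax heads averaged and, if
    ``attention_score_weighting``, scores modulated by the edge weight).
    ``train_embeddings`` makes the random input embeddings trainable —
    useful for transductive biomarker discovery, harmful for held-out
    prediction (patients then memorize their labels through their own
    embedding rows).  ``weight_decay`` adds L2 shrinkage to every
    parameter except the classifier bias.
    """

    epochs: int = 200
    lr: float = 1e-2
    neighbors_per_hop: tuple[int, ...] | int = 50
    hops: int = 2
    embedding_dim: int = 100
    seed: int = 0
    attention_mode: str = "uniform"
    self_loop: bool = True
    hidden_activation: str = "relu"
    train_embeddings: bool = False
    attention_score_weighting: bool = False
    attention_heads: int = 1
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.hops < 1:
            raise InputError("hops must be >= 1")
        if isinstance(self.neighbors_per_hop, (int, np.integer)):
            self.neighbors_per_hop = (int(self.neighbors_per_hop),) * self.hops
        else:
            self.neighbors_per_hop = tuple(int(k) for k in self.neighbors_per_hop)
        if len(self.neighbors_per_hop) != self.hops:
            raise InputError("neighbors_per_hop must have one entry per hop")
        if any(k < 1 for k in self.neighbors_per_hop):
            raise InputError("neighbors_per_hop entries must be >= 1")
        if self.embedding_dim < 1:
            raise InputError("embedding_dim must be >= 1")
        if self.epochs < 0:
            raise InputError("epochs must be >= 0")
        if self.attention_mode not in ("uniform", "learned"):
            raise InputError(f"unknown attention_mode {self.attention_mode!r}")
        if self.attention_heads < 1:
            raise InputError("attention_heads must be >= 1")


# ---------------------------------------------------------------------------
# functional operations (the model class builds on these)

def init_embeddings(graph: HeteroGraph, d: int = 100, seed: int = 0) -> EmbeddingSet:
    """Independent standard-normal vectors scaled by 1/sqrt(d) per node."""
    if d < 1:
        raise InputError(f"embedding dimension must be >= 1, got {d}")
    rng = np.random.default_rng(seed)
    vecs = rng.standard_normal((graph.n, d)) / np.sqrt(d)
    return EmbeddingSet(vectors=vecs, d=d, layer_index=0)


def sample_neighbors(graph: HeteroGraph, node: int, k_sample: int,
                     rng: np.random.Generator) -> np.ndarray:
    """All neighbors when degree <= k_sample, else a uniform subset without
    replacement; an isolated node yields an empty array."""
    if k_sample < 1:
        raise InputError("k_sample must be >= 1")
    nbrs, _ = graph.neighbors(node)
    if len(nbrs) <= k_sample:
        return np.sort(nbrs)
    return rng.choice(nbrs, size=k_sample, replace=False)


def uniform_attention(neighborhood) -> np.ndarray:
    """Eq-style uniform weights 1/|N(u)| over a nonempty neighborhood."""
    k = len(neighborhood)
    if k == 0:
        raise InputError("uniform attention is undefined for an empty neighborhood")
    return np.full(k, 1.0 / k)


def learned_attention(h_u: np.ndarray, neighbors: np.ndarray,
                      params: LayerParams,
                      edge_weights: np.ndarray | None = None) -> np.ndarray:
    """GAT-style additive attention row over ``neighbors``.

    score(u, v) = leaky-ReLU(a_dst . Wh_u + a_src . Wh_v), multiplied by the
    edge weight when given, then softmax-normalized over the neighborhood.
    """
    H = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if H.shape[0] == 0:
        raise InputError("learned attention is undefined for an empty neighborhood")
    if params.att_dst is None or params.att_src is None:
        raise InputError("LayerParams.att_dst/att_src are required for learned attention")
    a_dst = np.ravel(params.att_dst)[-params.W.shape[0]:] if np.ndim(params.att_dst) > 1 else np.ravel(params.att_dst)
    a_src = np.ravel(params.att_src)[-params.W.shape[0]:] if np.ndim(params.att_src) > 1 else np.ravel(params.att_src)
    zu = params.W @ np.asarray(h_u, dtype=float)
    Zv = H @ params.W.T
    raw = a_dst @ zu + Zv @ a_src
    scores = np.where(raw > 0, raw, _LEAKY_SLOPE * raw)
    if edge_weights is not None:
        scores = scores * np.asarray(edge_weights, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise NumericError("non-finite attention scores")
    return softmax(scores)


def aggregate_mean(h_u: np.ndarray, neighbors, W: np.ndarray,
                   activation: str = "identity") -> np.ndarray:
    """GraphSAGE mean update: sigma(W . mean({h_u} union {h_v}))."""
    act, _ = _ACTIVATIONS[activation]
    h_u = np.asarray(h_u, dtype=float)
    stack = [h_u] + [np.asarray(v, dtype=float) for v in neighbors]
    mean = np.mean(stack, axis=0)
    if W.shape[1] != mean.shape[0]:
        raise InputError(f"W has {W.shape[1]} input dims, embeddings have {mean.shape[0]}")
    return act(W @ mean)


def aggregate_attention(h_u: np.ndarray, neighbors, alpha: np.ndarray,
                        W: np.ndarray, activation: str = "identity",
                        self_loop: bool = True) -> np.ndarray:
    """Attention update: sigma(sum_v alpha_uv W h_v), optionally with a self term.

    When ``self_loop`` is on and ``alpha`` covers only the neighbors, the
    self node joins the aggregation set as an average-weight member: the
    neighbor weights are rescaled by k/(k+1) and the self weight is
    1/(k+1).  Under uniform alpha this reproduces the mean update exactly.
    An explicit length-(k+1) row (self weight last) is also accepted.
    """
    h_u = np.asarray(h_u, dtype=float)
    members = [np.asarray(v, dtype=float) for v in neighbors]
    alpha = np.asarray(alpha, dtype=float)
    k = len(members)
    if abs(alpha.sum() - 1.0) > 1e-6:
        raise InputError(f"attention row sums to {alpha.sum():.8f}, expected 1")
    if self_loop:
        if len(alpha) == k:
            alpha = np.concatenate([alpha * k / (k + 1), [1.0 / (k + 1)]])
        elif len(alpha) != k + 1:
            raise InputError("attention row length must be k or k+1 with self_loop")
        members = members + [h_u]
    elif len(alpha) != k:
        raise InputError("attention row length must match the neighborhood")
    act, _ = _ACTIVATIONS[activation]
    H = np.stack(members)
    return act(W @ (alpha @ H))


def classify(patient_embedding: np.ndarray, classifier_params) -> np.ndarray:
    """Softmax class probabilities from an embedding (or a batch of them)."""
    Wc, bc = classifier_params
    x = np.asarray(patient_embedding, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != Wc.shape[1]:
        raise InputError(f"embedding length {x.shape[1]} does not match classifier "
                         f"input {Wc.shape[1]}")
    probs = softmax(x @ Wc.T + bc, axis=1)
    return probs[0] if squeeze else probs


# ---------------------------------------------------------------------------
# vectorized message plumbing

@dataclass
class _Messages:
    """Directed message list (dst <- src) with weights and edge-type codes."""

    dst: np.ndarray
    src: np.ndarray
    w: np.ndarray
    et: np.ndarray


def _full_messages(graph: HeteroGraph, etype_codes: dict[str, int]) -> _Messages:
    e = graph.edges
    u, v = e["u"].to_numpy(), e["v"].to_numpy()
    w = e["weight"].to_numpy()
    codes = e["edge_type"].map(etype_codes).to_numpy(dtype=int)
    return _Messages(dst=np.concatenate([u, v]), src=np.concatenate([v, u]),
                     w=np.concatenate([w, w]), et=np.concatenate([codes, codes]))


def _sample_messages(msg: _Messages, k: int, n: int,
                     rng: np.random.Generator | None) -> _Messages:
    counts = np.bincount(msg.dst, minlength=n)
    if rng is None or counts.max(initial=0) <= k:
        return msg
    keys = rng.random(len(msg.dst))
    order = np.lexsort((keys, msg.dst))
    dst_sorted = msg.dst[order]
    starts = np.r_[0, np.cumsum(np.bincount(dst_sorted, minlength=n))][dst_sorted]
    pos = np.arange(len(dst_sorted)) - starts
    keep = order[pos < k]
    keep.sort()
    return _Messages(msg.dst[keep], msg.src[keep], msg.w[keep], msg.et[keep])


def _with_self_loops(msg: _Messages, n: int, self_code: int,
                     self_loop: bool) -> _Messages:
    """Append self messages (weight 1).  Without self loops, isolated nodes
    still get one so aggregation falls back to the node itself."""
    if self_loop:
        nodes = np.arange(n)
    else:
        present = np.bincount(msg.dst, minlength=n) > 0
        nodes = np.flatnonzero(~present)
        if len(nodes) == 0:
            return msg
    return _Messages(dst=np.concatenate([msg.dst, nodes]),
                     src=np.concatenate([msg.src, nodes]),
                     w=np.concatenate([msg.w, np.ones(len(nodes))]),
                     et=np.concatenate([msg.et, np.full(len(nodes), self_code)]))


def _hop_forward(H: np.ndarray, lp: LayerParams, msg: _Messages, n: int,
                 mode: str, score_weighting: bool = False) -> tuple[np.ndarray, dict]:
    """One aggregation hop over the message list; returns (H_next, cache)."""
    Z = H @ lp.W.T
    if mode == "uniform":
        counts = np.bincount(msg.dst, minlength=n)
        alpha = 1.0 / counts[msg.dst]
        raws = alphas = None
    else:
        A_d = _att3d(lp.att_dst)
        A_s = _att3d(lp.att_src)
        n_heads, n_et, _ = A_d.shape
        eti = msg.et % n_et
        raws, alphas = [], []
        for h in range(n_heads):
            # per-node score components against every edge-type vector (n x n_et)
            zd, zs = Z @ A_d[h].T, Z @ A_s[h].T
            raw = zd[msg.dst, eti] + zs[msg.src, eti]
            scores = np.where(raw > 0, raw, _LEAKY_SLOPE * raw)
            if score_weighting:
                scores = scores * msg.w
            if not np.all(np.isfinite(scores)):
                raise NumericError("non-finite attention scores")
            mx = np.full(n, -np.inf)
            np.maximum.at(mx, msg.dst, scores)
            ex = np.exp(scores - mx[msg.dst])
            denom = np.bincount(msg.dst, weights=ex, minlength=n)
            raws.append(raw)
            alphas.append(ex / denom[msg.dst])
        # head-averaged attention keeps rows normalized
        alpha = np.mean(alphas, axis=0)
    S = sp.csr_matrix((alpha * msg.w, (msg.dst, msg.src)), shape=(n, n))
    P = S @ Z
    act, act_grad = _ACTIVATIONS[lp.activation]
    cache = {"H_in": H, "Z": Z, "P": P, "alpha": alpha, "raws": raws,
             "alphas": alphas, "S": S, "msg": msg}
    return act(P), cache


def _hop_backward(dH_out: np.ndarray, lp: LayerParams, cache: dict, n: int,
                  mode: str, score_weighting: bool = False) -> tuple[np.ndarray, dict]:
    """Gradients of one hop; returns (dH_in, grads dict for this hop)."""
    _, act_grad = _ACTIVATIONS[lp.activation]
    msg: _Messages = cache["msg"]
    dP = dH_out * act_grad(cache["P"])
    dZ = cache["S"].T @ dP
    grads: dict[str, np.ndarray] = {}
    if mode == "learned":
        Z = cache["Z"]
        A_d = _att3d(lp.att_dst)
        A_s = _att3d(lp.att_src)
        n_heads, n_et, _ = A_d.shape
        eti = msg.et % n_et
        # gradient wrt the head-averaged attention, shared across heads
        dalpha = msg.w * (Z[msg.src] * dP[msg.dst]).sum(axis=1) / n_heads
        grads["att_dst"] = np.zeros_like(A_d)
        grads["att_src"] = np.zeros_like(A_s)
        for h in range(n_heads):
            alpha_h, raw_h = cache["alphas"][h], cache["raws"][h]
            g = alpha_h * dalpha
            seg = np.bincount(msg.dst, weights=g, minlength=n)
            ds = alpha_h * (dalpha - seg[msg.dst])
            draw = ds * np.where(raw_h > 0, 1.0, _LEAKY_SLOPE)
            if score_weighting:
                draw = draw * msg.w
            # score-vector gradients: sum draw_e * Z[endpoint] per edge type
            D_dst = sp.csr_matrix((draw, (eti, msg.dst)), shape=(n_et, n))
            D_src = sp.csr_matrix((draw, (eti, msg.src)), shape=(n_et, n))
            grads["att_dst"][h] = np.asarray(D_dst @ Z)
            grads["att_src"][h] = np.asarray(D_src @ Z)
            # embedding gradients through the scores: accumulate per-(node,
            # type) coefficients, one small matmul against the score vectors
            C_dst = np.bincount(msg.dst * n_et + eti, weights=draw,
                                minlength=n * n_et).reshape(n, n_et)
            C_src = np.bincount(msg.src * n_et + eti, weights=draw,
                                minlength=n * n_et).reshape(n, n_et)
            dZ = dZ + C_dst @ A_d[h] + C_src @ A_s[h]
    grads["W"] = dZ.T @ cache["H_in"]
    dH_in = dZ @ lp.W
    return dH_in, grads


def forward(graph: HeteroGraph, embeddings: EmbeddingSet,
            params: list[LayerParams], config: TrainConfig,
            rng: np.random.Generator | None = None,
            ) -> tuple[EmbeddingSet, AttentionMatrix, list[AttentionMatrix]]:
    """Run the multi-hop aggregation; returns (final embeddings for all
    nodes, last-hop attention, attention per hop).

    With ``rng=None`` (or sampling caps at or above the maximum degree) the
    pass is exhaustive and fully deterministic.
    """
    if len(params) != config.hops:
        raise InputError("one LayerParams per hop is required")
    etype_codes = _etype_codes(graph)
    full = _full_messages(graph, etype_codes)
    H = embeddings.vectors
    attn: list[AttentionMatrix] = []
    for hop in range(config.hops):
        msg = _sample_messages(full, config.neighbors_per_hop[hop], graph.n, rng)
        msg = _with_self_loops(msg, graph.n, etype_codes[SELF_EDGE_TYPE], config.self_loop)
        H, cache = _hop_forward(H, params[hop], msg, graph.n,
                                config.attention_mode,
                                config.attention_score_weighting)
        attn.append(AttentionMatrix(dst=msg.dst, src=msg.src,
                                    alpha=cache["alpha"], n_nodes=graph.n))
    out = EmbeddingSet(vectors=H, d=H.shape[1], layer_index=config.hops)
    return out, attn[-1], attn


def _etype_codes(graph: HeteroGraph) -> dict[str, int]:
    names = sorted(set(graph.edges["edge_type"])) if graph.m else []
    codes = {name: i for i, name in enumerate(names)}
    codes[SELF_EDGE_TYPE] = len(names)
    return codes


# ---------------------------------------------------------------------------
# the model / results pair

class MultiOmicsGNN:
    """Patient-classification GNN over a multi-omics knowledge graph.

    Parameters
    ----------
    graph : HeteroGraph
        Patients plus molecular features with weighted edges.
    labels : pandas.Series, optional
        Class label per patient (sample id -> label); defaults to
        ``graph.labels``.
    config : TrainConfig, optional
        Architecture and optimization settings.

    ``fit`` returns a :class:`GNNResults` carrying the trained parameters,
    final embeddings, attention weights, the loss trajectory and prediction
    helpers.
    """

    def __init__(self, graph: HeteroGraph, labels: pd.Series | None = None,
                 config: TrainConfig | None = None) -> None:
        self.graph = graph
        self.config = config or TrainConfig()
        labels = graph.labels if labels is None else labels
        if labels is None:
            raise InputError("patient labels are required (labels= or graph.labels)")
        self.patient_idx = self.graph.patient_indices
        patient_ids = [graph.node_ids[i] for i in self.patient_idx]
        missing = [p for p in patient_ids if p not in labels.index]
        if missing:
            raise InputError(f"no label for patient {missing[0]!r}")
        self.labels = labels.reindex(patient_ids)
        self.classes = tuple(sorted(self.labels.unique()))
        self._class_to_int = {c: i for i, c in enumerate(self.classes)}
        self.y = self.labels.map(self._class_to_int).to_numpy(dtype=int)
        self._etype_codes = _etype_codes(graph)
        self._full_msgs = _full_messages(graph, self._etype_codes)

    @classmethod
    def from_cohort(cls, cohort, config: TrainConfig | None = None,
                    normalize: str = "zscore_per_feature",
                    top_k_per_patient: int | None = None) -> "MultiOmicsGNN":
        """Build the knowledge graph from a synthetic cohort and wrap it."""
        graph = cohort_graph(cohort, normalize=normalize,
                             top_k_per_patient=top_k_per_patient)
        return cls(graph, labels=cohort.labels, config=config)

    # -- parameter initialization -----------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        d = cfg.embedding_dim
        n_et = len(self._etype_codes)
        params: dict[str, np.ndarray] = {
            "H0": rng.standard_normal((self.graph.n, d)) / np.sqrt(d),
        }
        for k in range(cfg.hops):
            limit = np.sqrt(6.0 / (d + d))
            params[f"W{k}"] = rng.uniform(-limit, limit, size=(d, d))
            if cfg.attention_mode == "learned":
                shape = (cfg.attention_heads, n_et, d)
                params[f"att_dst{k}"] = 0.1 * rng.standard_normal(shape)
                params[f"att_src{k}"] = 0.1 * rng.standard_normal(shape)
        n_classes = len(self.classes)
        limit = np.sqrt(6.0 / (d + n_classes))
        params["Wc"] = rng.uniform(-limit, limit, size=(n_classes, d))
        params["bc"] = np.zeros(n_classes)
        return params

    def _layer_params(self, params: dict[str, np.ndarray], hop: int) -> LayerParams:
        cfg = self.config
        activation = cfg.hidden_activation if hop < cfg.hops - 1 else "identity"
        return LayerParams(
            W=params[f"W{hop}"], activation=activation,
            att_dst=params.get(f"att_dst{hop}"), att_src=params.get(f"att_src{hop}"))

    # -- loss / gradients ---------------------------------------------------
    def _forward_pass(self, params: dict[str, np.ndarray],
                      msgs: list[_Messages]) -> tuple[np.ndarray, list[dict], np.ndarray]:
        H = params["H0"]
        caches = []
        for hop in range(self.config.hops):
            lp = self._layer_params(params, hop)
            H, cache = _hop_forward(H, lp, msgs[hop], self.graph.n,
                                    self.config.attention_mode,
                                    self.config.attention_score_weighting)
            caches.append(cache)
        logits = H[self.patient_idx] @ params["Wc"].T + params["bc"]
        return H, caches, logits

    def _loss_and_grads(self, params: dict[str, np.ndarray], msgs: list[_Messages],
                        train_mask: np.ndarray):
        n_train = int(train_mask.sum())
        H, caches, logits = self._forward_pass(params, msgs)
        probs = softmax(logits, axis=1)
        rows = np.flatnonzero(train_mask)
        eps = 1e-12
        loss = -np.mean(np.log(probs[rows, self.y[rows]] + eps))

        dlogits = np.zeros_like(probs)
        dlogits[rows] = probs[rows]
        dlogits[rows, self.y[rows]] -= 1.0
        dlogits /= n_train
        grads = {"Wc": dlogits.T @ H[self.patient_idx], "bc": dlogits.sum(axis=0)}
        dH = np.zeros_like(H)
        dH[self.patient_idx] = dlogits @ params["Wc"]
        for hop in range(self.config.hops - 1, -1, -1):
            lp = self._layer_params(params, hop)
            dH, hop_grads = _hop_backward(dH, lp, caches[hop], self.graph.n,
                                          self.config.attention_mode,
                                          self.config.attention_score_weighting)
            grads[f"W{hop}"] = hop_grads["W"]
            if "att_dst" in hop_grads:
                grads[f"att_dst{hop}"] = hop_grads["att_dst"]
                grads[f"att_src{hop}"] = hop_grads["att_src"]
        if self.config.train_embeddings:
            grads["H0"] = dH
        return loss, grads

    def _epoch_messages(self, rng: np.random.Generator | None) -> list[_Messages]:
        out = []
        for k in self.config.neighbors_per_hop:
            msg = _sample_messages(self._full_msgs, k, self.graph.n, rng)
            msg = _with_self_loops(msg, self.graph.n,
                                   self._etype_codes[SELF_EDGE_TYPE],
                                   self.config.self_loop)
            out.append(msg)
        return out

    # -- fitting -------------------------------------------------------------
    def fit(self, train_mask: np.ndarray | None = None) -> "GNNResults":
        """Train end-to-end on the labeled patients in ``train_mask``
        (boolean over patients, default: all) and return the results."""
        cfg = self.config
        n_pat = len(self.patient_idx)
        if train_mask is None:
            train_mask = np.ones(n_pat, dtype=bool)
        train_mask = np.asarray(train_mask)
        if train_mask.dtype != bool:
            m = np.zeros(n_pat, dtype=bool)
            m[np.asarray(train_mask, dtype=int)] = True
            train_mask = m
        if train_mask.sum() == 0:
            raise InputError("no labeled patients selected for training")

        ss = np.random.SeedSequence(cfg.seed)
        s_init, s_samp = ss.spawn(2)
        rng_init = np.random.default_rng(s_init)
        rng_samp = np.random.default_rng(s_samp)
        params = self._init_params(rng_init)

        # Adam state
        mom = {k: np.zeros_like(v) for k, v in params.items()}
        vel = {k: np.zeros_like(v) for k, v in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        losses = np.empty(cfg.epochs)
        for epoch in range(cfg.epochs):
            msgs = self._epoch_messages(rng_samp)
            loss, grads = self._loss_and_grads(params, msgs, train_mask)
            if not np.isfinite(loss):
                raise NumericError(f"non-finite loss at epoch {epoch}")
            losses[epoch] = loss
            t = epoch + 1
            for key, g in grads.items():
                if cfg.weight_decay and key != "bc":
                    g = g + cfg.weight_decay * params[key]
                mom[key] = b1 * mom[key] + (1 - b1) * g
                vel[key] = b2 * vel[key] + (1 - b2) * g * g
                mhat = mom[key] / (1 - b1 ** t)
                vhat = vel[key] / (1 - b2 ** t)
                params[key] = params[key] - cfg.lr * mhat / (np.sqrt(vhat) + eps)

        # deterministic full-neighborhood pass for the reported state
        full_msgs = [
            _with_self_loops(self._full_msgs, self.graph.n,
                             self._etype_codes[SELF_EDGE_TYPE], cfg.self_loop)
            for _ in range(cfg.hops)
        ]
        H, caches, logits = self._forward_pass(params, full_msgs)
        probs = softmax(logits, axis=1)
        attn = [AttentionMatrix(dst=m.dst, src=m.src, alpha=c["alpha"], n_nodes=self.graph.n)
                for m, c in zip(full_msgs, caches)]
        layer_params = [self._layer_params(params, k) for k in range(cfg.hops)]
        return GNNResults(
            model=self, params=params, layer_params=layer_params,
            classifier=(params["Wc"], params["bc"]),
            embeddings=EmbeddingSet(vectors=H, d=H.shape[1], layer_index=cfg.hops),
            attention_per_hop=attn, loss_history=losses,
            train_mask=train_mask, probs=probs)


def train(graph: HeteroGraph, labels: pd.Series, config: TrainConfig) -> "GNNResults":
    """Convenience wrapper: build the model and fit on all labeled patients."""
    return MultiOmicsGNN(graph, labels=labels, config=config).fit()


@dataclass
class GNNResults:
    """Trained state: parameters, embeddings, attention, loss trajectory."""

    model: MultiOmicsGNN
    params: dict[str, np.ndarray]
    layer_params: list[LayerParams]
    classifier: tuple[np.ndarray, np.ndarray]
    embeddings: EmbeddingSet
    attention_per_hop: list[AttentionMatrix]
    loss_history: np.ndarray
    train_mask: np.ndarray
    probs: np.ndarray

    @property
    def attention(self) -> AttentionMatrix:
        """Final-hop attention (the default read for biomarker scoring)."""
        return self.attention_per_hop[-1]

    def patient_embeddings(self) -> pd.DataFrame:
        idx = self.model.patient_idx
        return pd.DataFrame(self.embeddings.vectors[idx],
                            index=self.model.labels.index)

    def predict_proba(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=self.model.labels.index,
                            columns=list(self.model.classes))

    def predict(self) -> pd.Series:
        codes = self.probs.argmax(axis=1)
        return pd.Series([self.model.classes[c] for c in codes],
                         index=self.model.labels.index, name="predicted")

    def accuracy(self, mask: np.ndarray | None = None) -> float:
        """Fraction correct over ``mask`` (boolean over patients; default all)."""
        pred = self.probs.argmax(axis=1)
        hit = pred == self.model.y
        if mask is not None:
            hit = hit[np.asarray(mask, dtype=bool)]
        return float(hit.mean())

    def biomarker_scores(self, hop: int = -1, centered: bool = True):
        """Degree-amplified attention pair scores (see biomarkers module)."""
        from .biomarkers import degree_weighted_scores
        return degree_weighted_scores(self.attention_per_hop[hop],
                                      self.model.graph, centered=centered)

    def select_modules(self, rule: str = "percentile", value: float = 99.0,
                       hop: int = -1, centered: bool = True):
        from .biomarkers import select_modules
        return select_modules(self.biomarker_scores(hop=hop, centered=centered),
                              rule, value)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_history)
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy loss")
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        g = self.model.graph
        lines = [
            "Multi-omics knowledge-graph GNN",
            "=" * 48,
            f"nodes: {g.n}  edges: {g.m}  patients: {len(self.model.patient_idx)}",
            f"classes: {', '.join(self.model.classes)}",
            f"hops: {cfg.hops}  embedding dim: {cfg.embedding_dim}  "
            f"attention: {cfg.attention_mode}  self-loop: {cfg.self_loop}",
            f"neighbors/hop: {cfg.neighbors_per_hop}  epochs: {cfg.epochs}  "
            f"lr: {cfg.lr:g}",
            f"final loss: {self.loss_history[-1]:.4f}" if len(self.loss_history)
            else "final loss: n/a (0 epochs)",
            f"training accuracy: {self.accuracy(self.train_mask):.3f}",
        ]
        return "\n".join(lines)


def cohort_graph(cohort, normalize: str = "zscore_per_feature",
                 top_k_per_patient: int | None = None) -> HeteroGraph:
    """Knowledge graph of a synthetic cohort: its four layers plus the
    regulatory association tables of its network."""
    from .graph import AssociationTable, build_graph

    net = cohort.network
    associations = [
        AssociationTable("mirna", "mrna", list(net.mirna_targets)),
        AssociationTable("circrna", "mirna", list(net.circ_sponges)),
        AssociationTable("probe", "mrna", list(net.probe_genes)),
    ]
    return build_graph(list(cohort.matrices.values()), associations,
                       labels=cohort.labels, normalize=normalize,
                       top_k_per_patient=top_k_per_patient)
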