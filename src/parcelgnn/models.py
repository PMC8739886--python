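"""Vertex-classifier architectures: baseline MLP, GCN, GAT, JKGAT.

All models map an N x F feature matrix over a surface graph to an N x C
logit matrix. The baseline is a vertex-wise feed-forward network ignoring
the graph. The GCN uses first-order spectral filtering: each layer applies
the renormalized adjacency (self-loops added, symmetric degree
normalization), so an L-layer network has an L-hop receptive field. The GAT
learns per-edge attention weights: for head m at layer l, the attention node
i pays node j (j in the closed neighborhood of i) is a LeakyReLU of a
learned linear function of the concatenated projections (W h_i || W h_j),
softmax-normalized over the neighborhood; hidden layers concatenate heads,
the output layer averages them. The JKGAT stacks GAT blocks and aggregates
*all* layer embeddings per node (concatenation, max-pooling, or a
bidirectional-LSTM attention over the layer sequence) before a linear output
head, letting each vertex choose its own effective depth.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from parcelgnn import autograd as ag
from parcelgnn.autograd import Tensor, concat, masked_softmax, maximum
from parcelgnn.surface import SurfaceGraph

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "init_params",
    "closed_neighborhood_edges",
    "gcn_layer",
    "gat_layer",
    "jk_aggregate",
    "forward",
    "predict_probabilities",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("baseline", "gcn", "gat", "jkgat")
AGGREGATIONS = ("concat", "maxpool", "lstm")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 3 layers, 32 hidden
    channels, 4 attention heads, feature dropout 0.1, LSTM aggregation,
    LeakyReLU slope 0.2.
    """

    architecture: str
    in_features: int
    num_classes: int
    depth: int = 3
    hidden_channels: int = 32
    attention_heads: int = 4
    dropout: float = 0.1
    aggregation: str = "lstm"
    negative_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(
                f"unknown aggregation {self.aggregation!r}; choose from {AGGREGATIONS}"
            )
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.architecture in ("gat", "jkgat") and self.attention_heads < 1:
            raise ValueError("attention models need >= 1 head")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.in_features < 1 or self.num_classes < 2:
            raise ValueError("need in_features >= 1 and num_classes >= 2")


@dataclass
class TrainedModel:
    """A ModelSpec plus its learned parameters and training history."""

    spec: ModelSpec
    params: dict[str, Tensor]
    training_log: list[dict] = field(default_factory=list)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def weight_params(self) -> list[tuple[str, Tensor]]:
        """Parameters subject to L2 regularization (everything but biases)."""
        return [(k, v) for k, v in self.params.items() if not k.endswith(".b")]


# ---------------------------------------------------------------------------
# initialization

def _uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


def _lstm_params(rng, prefix: str, in_dim: int, hid: int, params: dict) -> None:
    params[f"{prefix}.Wx"] = Tensor(_uniform(rng, in_dim, 4 * hid, (in_dim, 4 * hid)), True)
    params[f"{prefix}.Wh"] = Tensor(_uniform(rng, hid, 4 * hid, (hid, 4 * hid)), True)
    params[f"{prefix}.b"] = Tensor(np.zeros(4 * hid), True)


def init_params(spec: ModelSpec, seed: int = 0) -> dict[str, Tensor]:
    """Seeded fan-based uniform initialization of all learnable parameters."""
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}
    f, k, c, m = spec.in_features, spec.hidden_channels, spec.num_classes, spec.attention_heads

    if spec.architecture in ("baseline", "gcn"):
        widths = [f] + [k] * (spec.depth - 1) + [c]
        for layer, (k_in, k_out) in enumerate(zip(widths[:-1], widths[1:])):
            params[f"layer{layer}.W"] = Tensor(_uniform(rng, k_in, k_out, (k_in, k_out)), True)
            params[f"layer{layer}.b"] = Tensor(np.zeros(k_out), True)
    elif spec.architecture == "gat":
        # hidden layers concatenate M heads of width k; final layer averages
        # M heads of width C
        widths = [f] + [m * k] * (spec.depth - 1)
        for layer in range(spec.depth):
            k_in = widths[layer]
            k_out = c if layer == spec.depth - 1 else k
            for head in range(m):
                p = f"layer{layer}.head{head}"
                params[f"{p}.W"] = Tensor(_uniform(rng, k_in, k_out, (k_in, k_out)), True)
                params[f"{p}.a_src"] = Tensor(_uniform(rng, k_out, 1, (k_out, 1)), True)
                params[f"{p}.a_dst"] = Tensor(_uniform(rng, k_out, 1, (k_out, 1)), True)
            params[f"layer{layer}.b"] = Tensor(np.zeros(k_out), True)
    elif spec.architecture == "jkgat":
        # every block (including the last) outputs M*k channels; the output
        # head after jumping-knowledge aggregation maps to C
        widths = [f] + [m * k] * (spec.depth - 1)
        for layer in range(spec.depth):
            k_in = widths[layer] if layer < len(widths) else m * k
            for head in range(m):
                p = f"layer{layer}.head{head}"
                params[f"{p}.W"] = Tensor(_uniform(rng, k_in, k, (k_in, k)), True)
                params[f"{p}.a_src"] = Tensor(_uniform(rng, k, 1, (k, 1)), True)
                params[f"{p}.a_dst"] = Tensor(_uniform(rng, k, 1, (k, 1)), True)
            params[f"layer{layer}.b"] = Tensor(np.zeros(k), True)
        emb = m * k
        if spec.aggregation == "concat":
            out_in = spec.depth * emb
        elif spec.aggregation == "maxpool":
            out_in = emb
        else:  # lstm
            _lstm_params(rng, "jk.lstm_fwd", emb, k, params)
            _lstm_params(rng, "jk.lstm_bwd", emb, k, params)
            params["jk.attn_u"] = Tensor(_uniform(rng, 2 * k, 1, (2 * k, 1)), True)
            out_in = emb
        params["out.W"] = Tensor(_uniform(rng, out_in, c, (out_in, c)), True)
        params["out.b"] = Tensor(np.zeros(c), True)
    return params


# ---------------------------------------------------------------------------
# graph operators (cached dense forms per graph)

_graph_cache: dict[int, tuple[SurfaceGraph, np.ndarray, np.ndarray, np.ndarray]] = {}


def _graph_operators(g: SurfaceGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Renormalized adjacency D̃^{-1/2}(A+I)D̃^{-1/2} (dense) and the directed
    closed-neighborhood edge list (centers, neighbors) including self-loops."""
    cached = _graph_cache.get(id(g))
    if cached is not None and cached[0] is g:
        return cached[1], cached[2], cached[3]
    a = g.adjacency.toarray().astype(np.float64)
    np.fill_diagonal(a, 1.0)
    deg = a.sum(axis=1)
    d = 1.0 / np.sqrt(deg)
    a_hat = a * d[:, None] * d[None, :]
    coo = g.adjacency.tocoo()
    n = g.num_vertices
    centers = np.concatenate([coo.row, np.arange(n)])
    neighbors = np.concatenate([coo.col, np.arange(n)])
    order = np.lexsort((neighbors, centers))
    centers, neighbors = centers[order], neighbors[order]
    if len(_graph_cache) > 64:
        _graph_cache.clear()
    _graph_cache[id(g)] = (g, a_hat, centers, neighbors)
    return a_hat, centers, neighbors


def closed_neighborhood_edges(g: SurfaceGraph) -> tuple[np.ndarray, np.ndarray]:
    """Directed (center, neighbor) edge list with self-loops, sorted by center."""
    _, centers, neighbors = _graph_operators(g)
    return centers, neighbors


def gcn_layer(h, g: SurfaceGraph, w, b=None, activation: float | None = None):
    """First-order graph convolution: Â H W (+ b), optional LeakyReLU(slope)."""
    h = Tensor._wrap(h)
    w = Tensor._wrap(w)
    if h.shape[0] != g.num_vertices:
        raise ValueError(f"H has {h.shape[0]} rows for a {g.num_vertices}-vertex graph")
    if h.shape[1] != w.shape[0]:
        raise ValueError(f"shape mismatch: H is {h.shape}, W is {w.shape}")
    a_hat, _, _ = _graph_operators(g)
    out = Tensor(a_hat) @ (h @ w)
    if b is not None:
        out = out + Tensor._wrap(b)
    if activation is not None:
        out = out.leaky_relu(activation)
    return out


def gat_layer(
    h,
    g: SurfaceGraph,
    w_heads: Sequence,
    a_heads: Sequence[tuple],
    *,
    mode: str = "concat",
    negative_slope: float = 0.2,
    bias=None,
    return_attention: bool = False,
):
    """Multi-head attention layer over closed vertex neighborhoods.

    For each head, the unnormalized attention node i pays node j is
    ``LeakyReLU(a^T (W h_i || W h_j))``, computed for j in N_i ∪ {i} and
    normalized by a softmax over that neighborhood; the node update is the
    attention-weighted sum of projected neighbors. ``mode`` controls the
    head merge: "concat" (hidden layers) or "average" (output layer).

    With ``return_attention`` the per-head normalized attention coefficients
    are returned as flat per-edge vectors ordered like
    ``closed_neighborhood_edges(g)``.
    """
    h = Tensor._wrap(h)
    n = g.num_vertices
    if h.shape[0] != n:
        raise ValueError(f"H has {h.shape[0]} rows for a {n}-vertex graph")
    _, centers, neighbors = _graph_operators(g)
    outs = []
    alphas = []
    for w, (a_src, a_dst) in zip(w_heads, a_heads):
        w = Tensor._wrap(w)
        a_src = Tensor._wrap(a_src)
        a_dst = Tensor._wrap(a_dst)
        z = h @ w  # N x k'
        # a^T (z_i || z_j) decomposes into a_src^T z_i + a_dst^T z_j
        s = (z @ a_src).reshape(-1)  # per-center term
        t = (z @ a_dst).reshape(-1)  # per-neighbor term
        scores = (s[centers] + t[neighbors]).leaky_relu(negative_slope)  # per edge
        alpha = ag.segment_softmax(scores, centers, n)  # normalized per center
        msgs = alpha.reshape(-1, 1) * z[neighbors]
        outs.append(ag.segment_sum(msgs, centers, n))
        alphas.append(alpha)
    if mode == "concat":
        out = concat(outs, axis=1)
    elif mode == "average":
        out = ag.stack_sum(outs) * (1.0 / len(outs))
    else:
        raise ValueError(f"unknown head merge mode {mode!r}")
    if bias is not None:
        b = Tensor._wrap(bias)
        if mode == "concat":
            out = out + concat([b] * len(outs), axis=0).reshape(1, -1)
        else:
            out = out + b
    if return_attention:
        return out, alphas
    return out


def _lstm_direction(seq: list[Tensor], params: dict, prefix: str) -> list[Tensor]:
    """Run an LSTM over the layer sequence; returns hidden state per step."""
    wx, wh, b = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"], params[f"{prefix}.b"]
    n = seq[0].shape[0]
    hid = wh.shape[0]
    h = Tensor(np.zeros((n, hid)))
    c = Tensor(np.zeros((n, hid)))
    states = []
    for x in seq:
        gates = x @ wx + h @ wh + b
        i = gates[:, :hid].sigmoid()
        f = gates[:, hid : 2 * hid].sigmoid()
        g_ = gates[:, 2 * hid : 3 * hid].tanh()
        o = gates[:, 3 * hid :].sigmoid()
        c = f * c + i * g_
        h = o * c.tanh()
        states.append(h)
    return states


def jk_aggregate(
    layer_embeddings: Sequence,
    mode: str,
    params: dict | None = None,
    *,
    return_attention: bool = False,
):
    """Combine per-layer node embeddings into one embedding per node.

    concat: global concatenation (N x L*k). maxpool: element-wise maximum
    over layers. lstm: a bidirectional LSTM reads the layer sequence and
    scores each layer per node; scores are softmax-normalized across layers
    (a convex combination) and the output is the attention-weighted sum of
    the layer embeddings.
    """
    embs = [Tensor._wrap(e) for e in layer_embeddings]
    if not embs:
        raise ValueError("no layer embeddings")
    if mode == "concat":
        out = concat(embs, axis=1) if len(embs) > 1 else embs[0]
        return (out, None) if return_attention else out
    if mode == "maxpool":
        out = embs[0]
        for e in embs[1:]:
            out = maximum(out, e)
        return (out, None) if return_attention else out
    if mode != "lstm":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if params is None:
        raise ValueError("lstm aggregation requires its learned parameters")
    fwd = _lstm_direction(embs, params, "jk.lstm_fwd")
    bwd = _lstm_direction(embs[::-1], params, "jk.lstm_bwd")[::-1]
    u = params["jk.attn_u"]
    scores = [concat([hf, hb], axis=1) @ u for hf, hb in zip(fwd, bwd)]  # each N x 1
    score_mat = concat(scores, axis=1)  # N x L
    mask = np.ones(score_mat.shape, dtype=bool)
    attn = masked_softmax(score_mat, mask, axis=1)  # N x L, rows sum to 1
    out = ag.stack_sum(
        [attn[:, l : l + 1] * e for l, e in enumerate(embs)]
    )
    if return_attention:
        return out, attn
    return out


# ---------------------------------------------------------------------------
# forward pass

def _dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    if rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * keep


def forward(
    model: TrainedModel,
    g: SurfaceGraph,
    x,
    *,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    return_attention: bool = False,
):
    """Compute N x C logits. Deterministic when ``train_mode`` is False.

    With ``train_mode`` dropout is applied to the input features of every
    layer, drawn from ``rng``.
    """
    spec = model.spec
    p = model.params
    values = x.values if hasattr(x, "values") else np.asarray(x, dtype=np.float64)
    if values.shape[1] != spec.in_features:
        raise ValueError(
            f"feature width mismatch: model expects {spec.in_features}, got {values.shape[1]}"
        )
    h = Tensor(values)
    drop = spec.dropout if train_mode else 0.0
    slope = spec.negative_slope
    jk_attn = None

    if spec.architecture == "baseline":
        for layer in range(spec.depth):
            h = _dropout(h, drop, rng)
            h = h @ p[f"layer{layer}.W"] + p[f"layer{layer}.b"]
            if layer < spec.depth - 1:
                h = h.leaky_relu(slope)
        logits = h
    elif spec.architecture == "gcn":
        for layer in range(spec.depth):
            h = _dropout(h, drop, rng)
            act = slope if layer < spec.depth - 1 else None
            h = gcn_layer(h, g, p[f"layer{layer}.W"], p[f"layer{layer}.b"], activation=act)
        logits = h
    elif spec.architecture == "gat":
        for layer in range(spec.depth):
            h = _dropout(h, drop, rng)
            heads_w = [p[f"layer{layer}.head{m}.W"] for m in range(spec.attention_heads)]
            heads_a = [
                (p[f"layer{layer}.head{m}.a_src"], p[f"layer{layer}.head{m}.a_dst"])
                for m in range(spec.attention_heads)
            ]
            last = layer == spec.depth - 1
            h = gat_layer(
                h,
                g,
                heads_w,
                heads_a,
                mode="average" if last else "concat",
                negative_slope=slope,
                bias=p[f"layer{layer}.b"],
            )
            if not last:
                h = h.leaky_relu(slope)
        logits = h
    else:  # jkgat
        embeddings = []
        for layer in range(spec.depth):
            h = _dropout(h, drop, rng)
            heads_w = [p[f"layer{layer}.head{m}.W"] for m in range(spec.attention_heads)]
            heads_a = [
                (p[f"layer{layer}.head{m}.a_src"], p[f"layer{layer}.head{m}.a_dst"])
                for m in range(spec.attention_heads)
            ]
            h = gat_layer(
                h, g, heads_w, heads_a, mode="concat", negative_slope=slope,
                bias=p[f"layer{layer}.b"],
            ).leaky_relu(slope)
            embeddings.append(h)
        agg, jk_attn = jk_aggregate(
            embeddings, spec.aggregation, p, return_attention=True
        )
        logits = agg @ p["out.W"] + p["out.b"]
    if return_attention:
        return logits, jk_attn
    return logits


def predict_probabilities(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a logit matrix (supports -inf masked entries)."""
    z = logits - np.max(logits, axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# serialization

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a checkpoint archive: spec + training log (JSON) and weights (npz)."""
    path = Path(path)
    arrays = {k: v.data for k, v in model.params.items()}
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("spec.json", json.dumps(asdict(model.spec)))
        zf.writestr("training_log.json", json.dumps(model.training_log))
        zf.writestr("weights.npz", buf.getvalue())


def load_model(path: str | Path) -> TrainedModel:
    with zipfile.ZipFile(Path(path), "r") as zf:
        spec = ModelSpec(**json.loads(zf.read("spec.json")))
        log = json.loads(zf.read("training_log.json"))
        with zf.open("weights.npz") as fh:
            npz = np.load(io.BytesIO(fh.read()))
            params = {k: Tensor(npz[k], True) for k in npz.files}
    return TrainedModel(spec=spec, params=params, training_log=log)
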