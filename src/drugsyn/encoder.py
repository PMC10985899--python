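"""Multi-head graph-attention encoder for molecular graphs.

Each layer computes, per attention head, a masked neighborhood softmax

    e_ij   = LeakyReLU( a_src · W h_i + a_dst · W h_j )
    α_ij   = softmax over j ∈ N(i) ∪ {i} of e_ij
    h'_i   = σ_d( Σ_j α_ij W h_j )

with heads concatenated on hidden layers and averaged on the final layer.
Self-loops are always included so isolated atoms have a well-defined
neighborhood. All math runs on padded batches ``[B, N, ·]`` with boolean
masks; single-graph entry points wrap a batch of one.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .chem import MolecularGraph

__all__ = [
    "GATLayerParams",
    "DrugEncoder",
    "attention_coefficients",
    "gat_layer",
    "encode_drug",
    "pad_graphs",
]


class GATLayerParams:
    """Learnable parameters of one graph-attention layer.

    ``weights[m]`` is the per-head linear map ``[in_dim, head_dim]`` and
    ``attn_src[m]``/``attn_dst[m]`` are the two halves of the attention
    vector aᵀ ∈ R^{2·head_dim} applied to the source/target projections.
    """

    def __init__(self, in_dim: int, head_dim: int, num_heads: int = 4,
                 *, concat_heads: bool = True, activation: str = "elu",
                 negative_slope: float = 0.2, rng: np.random.Generator | None = None):
        if num_heads < 1:
            raise ValueError("num_heads must be >= 1")
        if activation not in ("elu", "identity", "relu", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_dim + head_dim))
        self.in_dim = in_dim
        self.head_dim = head_dim
        self.num_heads = num_heads
        self.concat_heads = concat_heads
        self.activation = activation
        self.negative_slope = negative_slope
        self.weights = [Tensor(rng.normal(0, scale, (in_dim, head_dim)), requires_grad=True)
                        for _ in range(num_heads)]
        self.attn_src = [Tensor(rng.normal(0, scale, (head_dim,)), requires_grad=True)
                         for _ in range(num_heads)]
        self.attn_dst = [Tensor(rng.normal(0, scale, (head_dim,)), requires_grad=True)
                         for _ in range(num_heads)]

    @property
    def out_dim(self) -> int:
        return self.head_dim * self.num_heads if self.concat_heads else self.head_dim

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.attn_src, *self.attn_dst]

    def _apply_activation(self, t: Tensor) -> Tensor:
        if self.activation == "elu":
            return t.elu()
        if self.activation == "relu":
            return t.relu()
        if self.activation == "tanh":
            return t.tanh()
        return t


def pad_graphs(graphs: list[MolecularGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a list of graphs to common size.

    Returns ``(features [B,N,F], adj [B,N,N] bool, node_mask [B,N] bool)``.
    The adjacency includes self-loops; padded rows keep a self-loop so the
    masked softmax stays defined, and downstream code zeroes them via the
    node mask.
    """
    if not graphs:
        raise ValueError("cannot pad an empty graph list")
    n_max = max(g.num_atoms for g in graphs)
    f_dim = graphs[0].node_features.shape[1]
    feats = np.zeros((len(graphs), n_max, f_dim))
    adj = np.zeros((len(graphs), n_max, n_max), dtype=bool)
    mask = np.zeros((len(graphs), n_max), dtype=bool)
    for b, g in enumerate(graphs):
        n = g.num_atoms
        feats[b, :n] = g.node_features
        adj[b, :n, :n] = g.adjacency(self_loops=True) > 0
        mask[b, :n] = True
        # keep padded diagonals on so every softmax row has support
        for i in range(n, n_max):
            adj[b, i, i] = True
    return feats, adj, mask


def _head_attention(h: Tensor, adj: np.ndarray, params: GATLayerParams,
                    m: int) -> tuple[Tensor, Tensor]:
    """Attention matrix α ``[B,N,N]`` and projected features Wh ``[B,N,K']``
    for head ``m``."""
    wh = h @ params.weights[m]                               # [B,N,K']
    src = (wh * params.attn_src[m]).sum(axis=-1)             # [B,N]
    dst = (wh * params.attn_dst[m]).sum(axis=-1)             # [B,N]
    b, n = src.shape[0], src.shape[1]
    logits = (src.reshape(b, n, 1) + dst.reshape(b, 1, n)).leaky_relu(
        params.negative_slope)
    alpha = logits.softmax(axis=-1, mask=adj)
    return alpha, wh


def gat_layer_batch(h: Tensor, adj: np.ndarray, mask: np.ndarray,
                    params: GATLayerParams) -> Tensor:
    """One GAT layer on a padded batch; padded rows are zeroed."""
    if h.shape[-1] != params.in_dim:
        raise ValueError(
            f"input width {h.shape[-1]} incompatible with layer ({params.in_dim})")
    heads = []
    for m in range(params.num_heads):
        alpha, wh = _head_attention(h, adj, params, m)
        heads.append(alpha @ wh)
    if params.concat_heads:
        out = concat(heads, axis=-1)
    else:
        out = heads[0]
        for t in heads[1:]:
            out = out + t
        out = out * (1.0 / params.num_heads)
    out = params._apply_activation(out)
    return out * mask[..., None]


def attention_coefficients(embeddings: np.ndarray | Tensor, graph: MolecularGraph,
                           params: GATLayerParams) -> np.ndarray:
    """Per-head attention matrices ``[num_heads, N, N]`` for one graph.

    Row i is a distribution over N(i) ∪ {i}: entries outside the
    neighborhood are exactly zero and each row sums to one.
    """
    if graph.num_atoms < 1:
        raise ValueError("attention undefined for an empty graph")
    h = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    h = h.reshape(1, *h.shape)
    adj = graph.adjacency(self_loops=True)[None].astype(bool)
    out = np.stack([
        _head_attention(h, adj, params, m)[0].data[0]
        for m in range(params.num_heads)
    ])
    return out


def gat_layer(embeddings: np.ndarray | Tensor, graph: MolecularGraph,
              params: GATLayerParams) -> np.ndarray:
    """Single-graph GAT layer (returns a plain array)."""
    h = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    h = h.reshape(1, *h.shape)
    adj = graph.adjacency(self_loops=True)[None].astype(bool)
    mask = np.ones((1, graph.num_atoms), dtype=bool)
    return gat_layer_batch(h, adj, mask, params).data[0]


class DrugEncoder:
    """A stack of GAT layers mapping atom descriptors to node embeddings.

    Defaults follow the convention of this architecture family: two layers,
    64-dimensional heads, four heads concatenated on the hidden layer and
    averaged (identity activation) on the final one, so the output width
    equals ``hidden_dim``.
    """

    def __init__(self, in_dim: int, hidden_dim: int = 64, num_heads: int = 4,
                 depth: int = 2, negative_slope: float = 0.2,
                 rng: np.random.Generator | None = None):
        if depth < 1:
            raise ValueError("encoder needs at least one layer")
        rng = rng or np.random.default_rng(0)
        self.layers: list[GATLayerParams] = []
        width = in_dim
        for d in range(depth):
            last = d == depth - 1
            layer = GATLayerParams(
                width, hidden_dim, num_heads,
                concat_heads=not last,
                activation="identity" if last else "elu",
                negative_slope=negative_slope, rng=rng)
            self.layers.append(layer)
            width = layer.out_dim
        self.out_dim = width

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def encode_batch(self, feats: np.ndarray, adj: np.ndarray, mask: np.ndarray,
                     *, dropout: float = 0.0,
                     rng: np.random.Generator | None = None) -> Tensor:
        h = Tensor(feats)
        for d, layer in enumerate(self.layers):
            h = gat_layer_batch(h, adj, mask, layer)
            if dropout > 0 and rng is not None and d < len(self.layers) - 1:
                h = h.dropout(dropout, rng)
        return h

    def encode(self, graph: MolecularGraph) -> np.ndarray:
        """Final-layer node embeddings ``[num_atoms, out_dim]`` for one graph."""
        feats, adj, mask = pad_graphs([graph])
        return self.encode_batch(feats, adj, mask).data[0]


def encode_drug(graph: MolecularGraph, layer_stack: DrugEncoder) -> np.ndarray:
    """Functional alias for :meth:`DrugEncoder.encode`."""
    return layer_stack.encode(graph)
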