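"""Adaptive cross-attention graph aggregation for drug pairs.

Given final-layer node embeddings E_A, E_B of the two drugs in a
combination, each atom of one drug is scored against every atom of the
partner drug:

    S_A = softmax_i( Σ_j tanh( (E_A W_k) (E_B W_q)ᵀ )_{ij} )

The graph-level vector is the score-weighted sum of value-projected atoms
plus a residual mean, layer-normalized:

    g_x = Σ_i S_A,i (E_A W_v)_i
    G_x = norm( mean_i(E_A) + g_x )

The per-atom scores S_A are the interpretability signal exported in
attention reports: they say which substructures of a drug the model deems
important *in the context of its partner*.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "AAGAMParams",
    "cross_attention_scores",
    "attention_pool",
    "graph_readout",
    "layer_norm",
    "aggregate_pair",
]

_LN_EPS = 1e-5


class AAGAMParams:
    """Key/query/value projections, square on the embedding width.

    One parameter set serves both directions (A scored against B and B
    against A); pass ``tied=False`` for separate per-direction maps.
    """

    def __init__(self, dim: int, *, tied: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / dim)

        def make():
            return Tensor(rng.normal(0, scale, (dim, dim)), requires_grad=True)

        self.dim = dim
        self.tied = tied
        self.key_proj, self.query_proj, self.value_proj = make(), make(), make()
        if tied:
            self.key_proj_b = self.key_proj
            self.query_proj_b = self.query_proj
            self.value_proj_b = self.value_proj
        else:
            self.key_proj_b, self.query_proj_b, self.value_proj_b = (
                make(), make(), make())

    def parameters(self) -> list[Tensor]:
        params = [self.key_proj, self.query_proj, self.value_proj]
        if not self.tied:
            params += [self.key_proj_b, self.query_proj_b, self.value_proj_b]
        return params

    def direction(self, slot: str) -> tuple[Tensor, Tensor, Tensor]:
        if slot == "A":
            return self.key_proj, self.query_proj, self.value_proj
        return self.key_proj_b, self.query_proj_b, self.value_proj_b


def layer_norm(t: Tensor, axis: int = -1, eps: float = _LN_EPS) -> Tensor:
    """Zero-mean unit-variance normalization over the feature axis (no
    learnable affine). An all-zero input maps to zeros."""
    mu = t.mean(axis=axis, keepdims=True)
    centered = t - mu
    var = (centered * centered).mean(axis=axis, keepdims=True)
    return centered * ((var + eps) ** -0.5)


def cross_attention_scores_batch(e_self: Tensor, e_other: Tensor,
                                 mask_self: np.ndarray, mask_other: np.ndarray,
                                 params: AAGAMParams, slot: str = "A") -> Tensor:
    """Batched scores ``[B, N_self]``; padded atoms get exactly zero score."""
    if e_self.shape[-1] != params.dim or e_other.shape[-1] != params.dim:
        raise ValueError("embedding width does not match AAGAM projections")
    w_k, w_q, _ = params.direction(slot)
    keys = e_self @ w_k                                   # [B,Ns,K]
    queries = e_other @ w_q                               # [B,No,K]
    logits = (keys @ queries.swapaxes(-1, -2)).tanh()     # [B,Ns,No]
    logits = logits * mask_other[:, None, :]
    summed = logits.sum(axis=-1)                          # [B,Ns]
    return summed.softmax(axis=-1, mask=mask_self)


def attention_pool_batch(e_self: Tensor, scores: Tensor,
                         params: AAGAMParams, slot: str = "A") -> Tensor:
    """g = Σ_i score_i · (E W_v)_i, batched → ``[B, K]``."""
    _, _, w_v = params.direction(slot)
    values = e_self @ w_v                                 # [B,N,K]
    return (values * scores.reshape(*scores.shape, 1)).sum(axis=-2)


def graph_readout_batch(e_self: Tensor, g: Tensor, mask: np.ndarray) -> Tensor:
    """G = layernorm( masked mean over atoms of E + g ), batched."""
    counts = mask.sum(axis=-1, keepdims=True)             # [B,1]
    mean = (e_self * mask[..., None]).sum(axis=-2) * Tensor(1.0 / counts)
    return layer_norm(mean + g)


def aggregate_pair(e_a: Tensor, e_b: Tensor, mask_a: np.ndarray,
                   mask_b: np.ndarray, params: AAGAMParams
                   ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Full aggregation for a batch of drug pairs.

    Returns ``(G_x, G_y, S_A, S_B)`` — the two graph-level vectors and the
    two per-atom score vectors.
    """
    s_a = cross_attention_scores_batch(e_a, e_b, mask_a, mask_b, params, "A")
    s_b = cross_attention_scores_batch(e_b, e_a, mask_b, mask_a, params, "B")
    g_x = attention_pool_batch(e_a, s_a, params, "A")
    g_y = attention_pool_batch(e_b, s_b, params, "B")
    return (graph_readout_batch(e_a, g_x, mask_a),
            graph_readout_batch(e_b, g_y, mask_b), s_a, s_b)


# ---------------------------------------------------------------------------
# single-pair conveniences (plain arrays in, plain arrays out)

def _as_batch(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    return t.reshape(1, *t.shape)


def cross_attention_scores(e_self, e_other, params: AAGAMParams) -> np.ndarray:
    """Scores of one drug's atoms against a partner drug; sums to 1."""
    a, b = _as_batch(e_self), _as_batch(e_other)
    m_a = np.ones((1, a.shape[1]), dtype=bool)
    m_b = np.ones((1, b.shape[1]), dtype=bool)
    return cross_attention_scores_batch(a, b, m_a, m_b, params).data[0]


def attention_pool(e_self, scores, params: AAGAMParams) -> np.ndarray:
    out = attention_pool_batch(_as_batch(e_self), _as_batch(scores), params)
    return out.data[0]


def graph_readout(e_self, g) -> np.ndarray:
    e, gv = _as_batch(e_self), _as_batch(g)
    mask = np.ones((1, e.shape[1]), dtype=bool)
    return graph_readout_batch(e, gv, mask).data[0]
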