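"""Classification head and the dual-pass consistency-regularized loss.

The fused vector is mapped through a two-layer MLP to two logits and a
softmax. Training forwards every sample twice with independent dropout
masks (two subnetworks); the loss averages both cross-entropies and adds an
α-weighted symmetric KL divergence pushing the two predictive distributions
together:

    L = ½ [ CE(ŷ₁) + CE(ŷ₂) + α ( KL(ŷ₁‖ŷ₂) + KL(ŷ₂‖ŷ₁) ) ]

With dropout 0 the passes coincide, the KL term vanishes, and L reduces to
the plain cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossConfig",
    "PredictionHead",
    "SynergyPrediction",
    "cross_entropy",
    "kl_divergence",
    "dual_pass_loss",
]


@dataclass
class LossConfig:
    """Dual-pass loss settings: KL weight α ≥ 0 (optionally learnable via a
    softplus parameterization) and the log-clamp floor."""

    kl_weight: float = 1.0
    learnable_alpha: bool = False
    epsilon: float = 1e-12

    def __post_init__(self):
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class SynergyPrediction:
    """Two-class output for one triplet: P(synergistic), logits, argmax label."""

    prob_synergy: float
    logits: np.ndarray
    label_pred: int

    @property
    def probs(self) -> np.ndarray:
        return np.array([1.0 - self.prob_synergy, self.prob_synergy])


class PredictionHead:
    """Two-layer MLP → 2 logits → softmax, applied after the fusion stack."""

    def __init__(self, in_dim: int, hidden_dim: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        s1, s2 = np.sqrt(2.0 / in_dim), np.sqrt(2.0 / hidden_dim)
        self.w1 = Tensor(rng.normal(0, s1, (in_dim, hidden_dim)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.w2 = Tensor(rng.normal(0, s2, (hidden_dim, 2)), requires_grad=True)
        self.b2 = Tensor(np.zeros(2), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def logits(self, fused: Tensor, *, dropout: float = 0.0,
               rng: np.random.Generator | None = None) -> Tensor:
        h = (fused @ self.w1 + self.b1).relu()
        if dropout > 0 and rng is not None:
            h = h.dropout(dropout, rng)
        return h @ self.w2 + self.b2

    def probabilities(self, fused: Tensor, **kw) -> Tensor:
        """Class probabilities ``[B, 2]`` (column 1 = synergistic)."""
        return self.logits(fused, **kw).softmax(axis=-1)


def cross_entropy(prob, label, eps: float = 1e-12) -> Tensor:
    """Binary cross-entropy on the synergy-class probability.

    ``prob`` is P(synergistic) per sample (scalar or ``[B]`` tensor/array),
    ``label`` is 0/1. Logs are clamped at ``eps`` so endpoints stay finite.
    Returns the mean over the batch as a scalar tensor.
    """
    p = prob if isinstance(prob, Tensor) else Tensor(prob)
    y = np.asarray(label, dtype=np.float64)
    loss = -(Tensor(y) * p.log(eps) + Tensor(1.0 - y) * (1.0 - p).log(eps))
    return loss.mean()


def kl_divergence(p, q, eps: float = 1e-12) -> Tensor:
    """KL(p‖q) = Σ p (log p − log q) over the class axis, mean over batch.

    Non-negative by Gibbs' inequality; zero iff p = q (up to eps effects).
    """
    pt = p if isinstance(p, Tensor) else Tensor(p)
    qt = q if isinstance(q, Tensor) else Tensor(q)
    per = (pt * (pt.log(eps) - qt.log(eps))).sum(axis=-1)
    return per.mean()


def dual_pass_loss(probs1: Tensor, probs2: Tensor, labels: np.ndarray,
                   config: LossConfig, alpha: Tensor | None = None) -> Tensor:
    """Combine two stochastic forward passes into the training loss.

    ``probs1``/``probs2`` are ``[B, 2]`` class-probability tensors from two
    independent dropout draws of the same network. ``alpha`` overrides the
    fixed KL weight when α is learnable.
    """
    eps = config.epsilon
    p1 = probs1.reshape(-1, 2)
    p2 = probs2.reshape(-1, 2)
    pick_syn = Tensor(np.array([[0.0, 1.0]]))  # selects P(class 1) per row
    syn1 = (p1 * pick_syn).sum(axis=-1)
    syn2 = (p2 * pick_syn).sum(axis=-1)
    ce = cross_entropy(syn1, labels, eps) + cross_entropy(syn2, labels, eps)
    kl = kl_divergence(p1, p2, eps) + kl_divergence(p2, p1, eps)
    a = alpha if alpha is not None else Tensor(config.kl_weight)
    return (ce + a * kl) * 0.5
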