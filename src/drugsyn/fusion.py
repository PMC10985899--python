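"""Gated multi-source feature interaction (highway-style fusion).

The fused vector F = [G_x ‖ G_y ‖ v] (two drug embeddings and the cell
embedding) passes through stacked layers of the form

    y = g ⊙ w + (1 − g) ⊙ q
    g = sigmoid(gate(F)),  w = relu(nonlinear(F)),  q = linear(F)

where gate/nonlinear/linear are width-preserving affine maps. When the gate
saturates at 1 the layer reduces to the relu branch; at 0 it reduces to the
linear carry branch, and with an identity carry the stack passes input
through unchanged (classic highway behavior).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["MFICParams", "mfic_layer", "mfic_stack"]


class _Affine:
    def __init__(self, dim: int, rng: np.random.Generator, *,
                 bias_init: float = 0.0, identity: bool = False):
        self.identity = identity
        if identity:
            self.w = self.b = None
            return
        scale = np.sqrt(1.0 / dim)
        self.w = Tensor(rng.normal(0, scale, (dim, dim)), requires_grad=True)
        self.b = Tensor(np.full(dim, bias_init, dtype=np.float64), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        return x @ self.w + self.b

    def parameters(self) -> list[Tensor]:
        return [] if self.identity else [self.w, self.b]


class MFICParams:
    """Parameters of a stack of gated fusion layers.

    ``gate_bias_init`` defaults to −1, biasing early training toward the
    linear carry path. ``parametric_gate=False`` gives the ablation variant
    g = sigmoid(F) with no learnable gate. ``identity_carry=True`` makes the
    linear branch the identity map.
    """

    def __init__(self, dim: int, depth: int = 2, *, gate_bias_init: float = -1.0,
                 parametric_gate: bool = True, identity_carry: bool = False,
                 rng: np.random.Generator | None = None):
        if depth < 1:
            raise ValueError("MFIC depth must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.depth = depth
        self.parametric_gate = parametric_gate
        self.layers: list[dict[str, _Affine | None]] = []
        for _ in range(depth):
            self.layers.append({
                "gate": _Affine(dim, rng, bias_init=gate_bias_init)
                        if parametric_gate else None,
                "nonlinear": _Affine(dim, rng),
                "linear": _Affine(dim, rng, identity=identity_carry),
            })

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            for aff in layer.values():
                if aff is not None:
                    out.extend(aff.parameters())
        return out


def mfic_layer(f: Tensor, params: MFICParams, layer_index: int = 0) -> Tensor:
    """One gated blend; output width equals input width, and every component
    lies between the corresponding relu-branch and linear-branch values."""
    if f.shape[-1] != params.dim:
        raise ValueError(f"fused width {f.shape[-1]} != MFIC width {params.dim}")
    layer = params.layers[layer_index]
    gate = layer["gate"](f).sigmoid() if layer["gate"] is not None else f.sigmoid()
    w = layer["nonlinear"](f).relu()
    q = layer["linear"](f)
    return gate * w + (1.0 - gate) * q


def mfic_stack(f: Tensor, params: MFICParams) -> Tensor:
    """Depth-fold composition of :func:`mfic_layer`."""
    for d in range(params.depth):
        f = mfic_layer(f, params, d)
    return f
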