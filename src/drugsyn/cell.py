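"""Cell-line expression handling: TPM normalization, gene-panel selection,
and a tanh multilayer-perceptron embedding.

Expression arrives as a genes × cell-lines matrix, either already TPM or as
raw counts plus per-gene lengths. Profiles are restricted to a fixed gene
panel (the landmark-style reduced feature space; default size 954) and
embedded with a bias-free tanh MLP so the cell vector lands in the same
width as the drug graph embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor

__all__ = [
    "ExpressionMatrix",
    "CellLineProfile",
    "CellMLPParams",
    "tpm_normalize",
    "select_genes",
    "encode_cell",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes × cell-lines numeric matrix with unique row/column ids."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=np.float64),
                   [str(g) for g in df.index], [str(c) for c in df.columns])

    def profile(self, cell_id: str) -> "CellLineProfile":
        j = self.cell_ids.index(cell_id)
        return CellLineProfile(self.values[:, j].copy(), cell_id)


@dataclass
class CellLineProfile:
    """One cell line's expression vector over the gene panel."""

    values: np.ndarray
    cell_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


def tpm_normalize(counts: ExpressionMatrix, gene_lengths_kb: np.ndarray
                  ) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    Per cell line: length-normalize counts to rates ``count/length``, then
    scale rates to sum to 10⁶. Gene lengths are in kilobases and must align
    with ``counts.gene_ids``. An all-zero library yields an all-zero column
    (warned, not fatal).
    """
    lengths = np.asarray(gene_lengths_kb, dtype=np.float64).ravel()
    if lengths.shape[0] != len(counts.gene_ids):
        raise ValueError("gene_lengths length does not match gene_ids")
    if np.any(lengths <= 0):
        bad = [counts.gene_ids[i] for i in np.where(lengths <= 0)[0][:5]]
        raise ValueError(f"non-positive gene length for genes {bad}")
    if np.any(counts.values < 0):
        raise ValueError("counts must be non-negative")
    rates = counts.values / lengths[:, None]
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning("all-zero expression column(s): %s",
                       [counts.cell_ids[j] for j in np.where(zero_cols)[0]])
    safe = np.where(zero_cols, 1.0, totals)
    tpm = rates / safe * 1e6
    tpm[:, zero_cols] = 0.0
    return ExpressionMatrix(tpm, list(counts.gene_ids), list(counts.cell_ids))


def select_genes(matrix: ExpressionMatrix, panel: list[str]) -> ExpressionMatrix:
    """Restrict rows to a gene panel, in panel order.

    Panel duplicates collapse to their first occurrence; panel genes absent
    from the matrix are dropped with a warning. An empty intersection is an
    error.
    """
    if not panel:
        raise ValueError("gene panel is empty")
    seen: set[str] = set()
    ordered = [g for g in panel if not (g in seen or seen.add(g))]
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    keep = [g for g in ordered if g in index]
    missing = [g for g in ordered if g not in index]
    if not keep:
        raise ValueError("no panel genes found in the expression matrix")
    if missing:
        logger.warning("panel genes missing from expression matrix: %s", missing)
    rows = [index[g] for g in keep]
    return ExpressionMatrix(matrix.values[rows], keep, list(matrix.cell_ids))


class CellMLPParams:
    """Bias-free tanh MLP weights: panel width → hidden widths → embed width.

    Every layer is tanh-activated, so the output lies strictly inside
    (−1, 1) componentwise. ``use_bias`` adds per-layer bias vectors.
    """

    def __init__(self, in_dim: int, hidden_dims: tuple[int, ...] = (256,),
                 out_dim: int = 64, *, use_bias: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        widths = [in_dim, *hidden_dims, out_dim]
        self.widths = widths
        self.use_bias = use_bias
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for a, b in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(1.0 / a)
            self.weights.append(Tensor(rng.normal(0, scale, (a, b)), requires_grad=True))
            if use_bias:
                self.biases.append(Tensor(np.zeros(b), requires_grad=True))

    @classmethod
    def from_weights(cls, weights: list[np.ndarray]) -> "CellMLPParams":
        obj = cls.__new__(cls)
        obj.weights = [Tensor(w, requires_grad=True) for w in weights]
        obj.biases = []
        obj.use_bias = False
        obj.widths = [weights[0].shape[0]] + [w.shape[1] for w in weights]
        return obj

    def parameters(self) -> list[Tensor]:
        return [*self.weights, *self.biases]


def encode_cell_batch(profiles: Tensor, params: CellMLPParams, *,
                      dropout: float = 0.0,
                      rng: np.random.Generator | None = None) -> Tensor:
    """Embed a batch of profiles ``[B, panel]`` → ``[B, embed]``."""
    if profiles.shape[-1] != params.widths[0]:
        raise ValueError(
            f"profile width {profiles.shape[-1]} != MLP input {params.widths[0]}")
    h = profiles
    for i, w in enumerate(params.weights):
        h = h @ w
        if params.use_bias:
            h = h + params.biases[i]
        h = h.tanh()
        if dropout > 0 and rng is not None and i < len(params.weights) - 1:
            h = h.dropout(dropout, rng)
    return h


def encode_cell(profile: CellLineProfile, params: CellMLPParams) -> np.ndarray:
    """Embed a single cell-line profile; output strictly inside (−1, 1)."""
    t = Tensor(profile.values.reshape(1, -1))
    return encode_cell_batch(t, params).data[0]
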