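"""File formats and run configuration.

Everything is delimited text: drug tables and triplet lists as CSV,
expression matrices as CSV with genes in rows and a header of cell ids,
gene panels as one id per line, attention reports as CSV. Run
configuration is YAML validated against the known keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cell import ExpressionMatrix
from .evaluate import TripletSample, label_by_loewe
from .model import ModelConfig

__all__ = [
    "read_triplets",
    "triplets_from_frame",
    "write_triplets",
    "read_expression",
    "write_expression",
    "read_gene_panel",
    "read_drug_table",
    "write_drug_table",
    "AttentionRow",
    "write_attention_report",
    "read_attention_report",
    "load_config",
    "config_hash",
]

logger = logging.getLogger(__name__)


class TripletFormatError(ValueError):
    """A triplet file violates the expected schema."""


def triplets_from_frame(df: pd.DataFrame) -> list[TripletSample]:
    """Build samples from a DataFrame with drug_a, drug_b, cell_line and
    either a ``label`` or a ``loewe_score`` column.

    Scores route through the Loewe rule; dead-zone rows (score in [0, 10])
    are dropped with a log entry. Malformed rows raise with their row
    number.
    """
    required = {"drug_a", "drug_b", "cell_line"}
    missing = required - set(df.columns)
    if missing:
        raise TripletFormatError(f"missing required column(s): {sorted(missing)}")
    has_label = "label" in df.columns
    has_score = "loewe_score" in df.columns
    if not has_label and not has_score:
        raise TripletFormatError(
            "file must contain a 'label' or a 'loewe_score' column")
    samples: list[TripletSample] = []
    dropped = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        a, b, c = str(row.drug_a), str(row.drug_b), str(row.cell_line)
        if a == b:
            raise TripletFormatError(f"row {row_no}: self-pair {a!r}")
        score = None
        if has_label and not pd.isna(getattr(row, "label", np.nan)):
            try:
                label = int(getattr(row, "label"))
            except (TypeError, ValueError) as exc:
                raise TripletFormatError(
                    f"row {row_no}: non-numeric label {getattr(row, 'label')!r}"
                ) from exc
        else:
            raw = getattr(row, "loewe_score")
            try:
                score = float(raw)
            except (TypeError, ValueError) as exc:
                raise TripletFormatError(
                    f"row {row_no}: non-numeric loewe_score {raw!r}") from exc
            try:
                maybe = label_by_loewe(score)
            except ValueError as exc:
                raise TripletFormatError(f"row {row_no}: {exc}") from exc
            if maybe is None:
                dropped += 1
                logger.info("row %d: loewe_score %.3g in dead zone [0, 10], dropped",
                            row_no, score)
                continue
            label = maybe
        try:
            samples.append(TripletSample(a, b, c, label, score))
        except ValueError as exc:
            raise TripletFormatError(f"row {row_no}: {exc}") from exc
    if dropped:
        logger.info("dropped %d dead-zone row(s)", dropped)
    return samples


def read_triplets(path) -> list[TripletSample]:
    """Read a delimited triplet file (CSV/TSV sniffed by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return triplets_from_frame(pd.read_csv(path, sep=sep))


def write_triplets(samples: list[TripletSample], path) -> None:
    pd.DataFrame([
        {"drug_a": s.drug_a, "drug_b": s.drug_b, "cell_line": s.cell,
         "label": s.label,
         **({"loewe_score": s.loewe_score} if s.loewe_score is not None else {})}
        for s in samples
    ]).to_csv(path, index=False)


def read_expression(path) -> ExpressionMatrix:
    """Genes-in-rows CSV with a header row of cell ids."""
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix.from_frame(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path)


def read_gene_panel(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    panel = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not panel:
        raise ValueError(f"gene panel file {path} is empty")
    return panel


def read_drug_table(path) -> dict[str, str]:
    df = pd.read_csv(path)
    if "drug_id" not in df.columns or "smiles" not in df.columns:
        raise ValueError("drug table needs 'drug_id' and 'smiles' columns")
    return dict(zip(df["drug_id"].astype(str), df["smiles"].astype(str)))


def write_drug_table(drugs: dict[str, str], path) -> None:
    pd.DataFrame({"drug_id": list(drugs), "smiles": list(drugs.values())}
                 ).to_csv(path, index=False)


# -- attention reports --------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AttentionRow:
    """One atom's importance score within one triplet's drug."""

    triplet_id: str
    drug_slot: str  # "A" or "B"
    atom_index: int
    element: str
    score: float


def write_attention_report(rows: list[AttentionRow], path) -> None:
    """Write per-atom attention scores as CSV (round-trip stable to 1e-9)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    df.to_csv(path, index=False, float_format="%.12g")


def read_attention_report(path) -> list[AttentionRow]:
    df = pd.read_csv(path)
    return [AttentionRow(str(r.triplet_id), str(r.drug_slot), int(r.atom_index),
                         str(r.element), float(r.score))
            for r in df.itertuples(index=False)]


# -- run configuration --------------------------------------------------------

_EXTRA_CONFIG_KEYS = {"seed", "cv", "augment", "gene_panel"}


def load_config(path) -> tuple[ModelConfig, dict]:
    """Load a YAML run config; unknown keys are rejected.

    Returns ``(ModelConfig, extras)`` where extras holds run-level keys
    (seed, cv, augment, gene_panel).
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(raw) - known - _EXTRA_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    extras = {k: raw.pop(k) for k in list(raw) if k in _EXTRA_CONFIG_KEYS}
    return ModelConfig(**raw), extras


def config_hash(config: ModelConfig, seed: int) -> str:
    """Short reproducibility fingerprint of config + seed."""
    blob = json.dumps({**dataclasses.asdict(config), "seed": seed},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
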