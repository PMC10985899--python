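"""Dataset labeling, splitting, order augmentation, and classification metrics.

Labels come from Loewe-additivity synergy scores with a conservative dead
zone: a combination scoring above 10 is synergistic, below 0 antagonistic,
and scores in [0, 10] are discarded as too noisy to call. Evaluation
reports AUROC, AUPR, accuracy, balanced accuracy, precision, sensitivity,
specificity and Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as _scipy_stats
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "TripletSample",
    "ConfusionCounts",
    "EvalReport",
    "label_by_loewe",
    "split_dataset",
    "augment_order",
    "swap_order",
    "compute_metrics",
    "order_sensitivity",
]

LOEWE_SYNERGY_THRESHOLD = 10.0
LOEWE_ANTAGONISM_THRESHOLD = 0.0


@dataclass(frozen=True)
class TripletSample:
    """One (drug A, drug B, cell line) unit of training/prediction."""

    drug_a: str
    drug_b: str
    cell: str
    label: int
    loewe_score: float | None = None

    def __post_init__(self):
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-combination {self.drug_a!r} is not a valid pair")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (antagonistic) or 1 (synergistic)")

    def swapped(self) -> "TripletSample":
        return TripletSample(self.drug_b, self.drug_a, self.cell,
                             self.label, self.loewe_score)


def label_by_loewe(score: float) -> int | None:
    """Map a Loewe synergy score to a binary label.

    Returns 1 (synergistic) for score > 10, 0 (antagonistic) for score < 0,
    and ``None`` for the discarded dead zone [0, 10].
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        raise ValueError("Loewe score is NaN or missing")
    if score > LOEWE_SYNERGY_THRESHOLD:
        return 1
    if score < LOEWE_ANTAGONISM_THRESHOLD:
        return 0
    return None


def split_dataset(samples: list[TripletSample], seed: int, *,
                  test_fraction: float = 0.1, n_folds: int = 5
                  ) -> tuple[list[TripletSample], list[TripletSample],
                             list[tuple[list[int], list[int]]]]:
    """Stratified 90/10 train/test split plus stratified CV folds of train.

    Returns ``(train, test, folds)`` where each fold is a pair of index
    lists (fit, validation) into ``train``. Deterministic for a fixed seed.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to split")
    labels = np.array([s.label for s in samples])
    idx_train, idx_test = train_test_split(
        np.arange(len(samples)), test_size=test_fraction,
        stratify=labels, random_state=seed)
    train = [samples[i] for i in idx_train]
    test = [samples[i] for i in idx_test]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_train = np.array([s.label for s in train])
    folds = [(list(map(int, fit)), list(map(int, val)))
             for fit, val in skf.split(np.zeros(len(train)), y_train)]
    return train, test, folds


def augment_order(samples: list[TripletSample]) -> list[TripletSample]:
    """Append the (B, A, cell) twin of every sample; labels unchanged."""
    return list(samples) + [s.swapped() for s in samples]


def swap_order(samples: list[TripletSample]) -> list[TripletSample]:
    """The order-swapped copy of a sample list (for sensitivity analysis)."""
    return [s.swapped() for s in samples]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, labels: np.ndarray, predicted: np.ndarray
                         ) -> "ConfusionCounts":
        labels = np.asarray(labels).astype(int)
        predicted = np.asarray(predicted).astype(int)
        return cls(
            tp=int(np.sum((labels == 1) & (predicted == 1))),
            fp=int(np.sum((labels == 0) & (predicted == 1))),
            tn=int(np.sum((labels == 0) & (predicted == 0))),
            fn=int(np.sum((labels == 1) & (predicted == 0))),
        )


@dataclass(frozen=True)
class EvalReport:
    """Scalar classification metrics for one evaluation pass."""

    auroc: float
    aupr: float
    acc: float
    bacc: float
    prec: float
    tpr: float
    tnr: float
    kappa: float
    n: int

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa from the confusion table: (p_o − p_e)/(1 − p_e) with
    p_e the chance-agreement rate from the marginals."""
    n = c.total
    p_o = (c.tp + c.tn) / n
    p_pos = ((c.tp + c.fn) / n) * ((c.tp + c.fp) / n)
    p_neg = ((c.tn + c.fp) / n) * ((c.tn + c.fn) / n)
    p_e = p_pos + p_neg
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def compute_metrics(scores: np.ndarray, labels: np.ndarray, *,
                    threshold: float = 0.5) -> EvalReport:
    """Full metric set from predicted synergy probabilities and 0/1 labels.

    Confusion-based metrics threshold at 0.5; AUROC/AUPR are rank-based
    (midrank tie handling). Raises if labels contain a single class, since
    the ranking metrics are undefined there.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    predicted = (scores >= threshold).astype(int)
    c = ConfusionCounts.from_predictions(labels, predicted)
    tpr = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    tnr = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    return EvalReport(
        auroc=float(_skm.roc_auc_score(labels, scores)),
        aupr=float(_skm.average_precision_score(labels, scores)),
        acc=(c.tp + c.tn) / c.total,
        bacc=(tpr + tnr) / 2.0,
        prec=prec,
        tpr=tpr,
        tnr=tnr,
        kappa=_kappa(c),
        n=c.total,
    )


def order_sensitivity(scores_ab: np.ndarray, scores_ba: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Pearson correlation between predictions under the two drug orders.

    Returns ``(r, paired)`` where ``paired`` is the [n, 2] score scatter
    for export. Degenerate constant inputs that are exactly equal count as
    perfectly correlated (r = 1).
    """
    a = np.asarray(scores_ab, dtype=np.float64).ravel()
    b = np.asarray(scores_ba, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired predictions")
    paired = np.column_stack([a, b])
    if np.allclose(a, b):
        return 1.0, paired
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0, paired
    r, _ = _scipy_stats.pearsonr(a, b)
    return float(r), paired
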