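"""Self-contained synthetic fixtures: drugs, expression profiles, and
planted-signal synergy labels.

The generator emulates the statistical shape of a combination-screen
dataset without any downloads: drugs are drawn from a curated pool of small
valid SMILES, cell-line expression is i.i.d. Gaussian over a configurable
gene panel (already on a normalized scale), and binary synergy labels are
planted through a logistic link that couples a graph-visible drug property
(aromatic-atom fraction of both drugs) with a cell feature (mean expression
over a designated gene subset). Recovering the labels therefore requires
both the molecular-graph branch and the expression branch of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .cell import ExpressionMatrix
from .chem import smiles_to_graph
from .evaluate import TripletSample

__all__ = [
    "SMILES_POOL",
    "SyntheticConfig",
    "PlantedRule",
    "generate_drug_library",
    "generate_expression",
    "generate_triplets",
    "generate_dataset",
]

#: Curated small molecules (name, SMILES); all parse to >= 1 heavy atom and
#: span aromatic and aliphatic chemistry so the planted drug feature varies.
SMILES_POOL: tuple[tuple[str, str], ...] = (
    ("ethanol", "CCO"),
    ("acetone", "CC(C)=O"),
    ("acetic_acid", "CC(=O)O"),
    ("urea", "NC(N)=O"),
    ("glycine", "NCC(=O)O"),
    ("isopropanol", "CC(C)O"),
    ("diethyl_ether", "CCOCC"),
    ("cyclohexane", "C1CCCCC1"),
    ("piperidine", "C1CCNCC1"),
    ("morpholine", "C1COCCN1"),
    ("dimethyl_sulfoxide", "CS(C)=O"),
    ("acetamide", "CC(N)=O"),
    ("lactic_acid", "CC(O)C(=O)O"),
    ("glycerol", "OCC(O)CO"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("benzoic_acid", "O=C(O)c1ccccc1"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("fluorobenzene", "Fc1ccccc1"),
    ("bromobenzene", "Brc1ccccc1"),
    ("anisole", "COc1ccccc1"),
    ("styrene", "C=Cc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("purine", "c1nc2[nH]cnc2cn1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults match the desk-scale conditions the package is validated
    under: a 30-drug library, 20 cell lines with 954-gene profiles (the
    landmark-panel size), 1,000 labeled triplets, planted-signal strength
    3.0 and link noise 0.5.
    """

    n_drugs: int = 30
    n_cells: int = 20
    n_genes: int = 954
    n_triplets: int = 1000
    noise_sd: float = 0.5
    signal_strength: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_cells, self.n_genes, self.n_triplets) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PlantedRule:
    """The hidden label-generating function.

    label ~ Bernoulli( sigmoid( s · (z(arom_A) + z(arom_B) + z(cell_mean))
    + ε ) ), where arom is each drug's aromatic-atom fraction, cell_mean is
    the mean expression over ``gene_subset`` genes, z(·) is empirical
    standardization over the sampled triplets (centering prevalence at
    0.5), s is ``signal_strength`` and ε ~ N(0, noise_sd).
    """

    signal_strength: float = 3.0
    noise_sd: float = 0.5
    gene_subset: int = 50

    def bayes_scores(self, arom_a, arom_b, cell_feat) -> np.ndarray:
        """The noise-free planted score (an oracle predictor for tests)."""
        z = _zscore(np.asarray(arom_a)) + _zscore(np.asarray(arom_b)) \
            + _zscore(np.asarray(cell_feat))
        return z


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def generate_drug_library(n_drugs: int, seed: int) -> dict[str, str]:
    """Deterministic sample without replacement from the curated pool.

    Returns ``{drug_id: smiles}``; every entry is guaranteed parsable.
    """
    if n_drugs > len(SMILES_POOL):
        raise ValueError(
            f"n_drugs={n_drugs} exceeds the curated pool ({len(SMILES_POOL)})")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(SMILES_POOL), size=n_drugs, replace=False)
    return {SMILES_POOL[i][0]: SMILES_POOL[i][1] for i in sorted(picks)}


def generate_expression(n_cells: int, n_genes: int, seed: int) -> ExpressionMatrix:
    """I.i.d. standard-normal profiles (already normalized-scale), genes
    ``g0001…`` × cells ``cell01…``; bitwise deterministic per seed."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_cells))
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    cells = [f"cell{j + 1:02d}" for j in range(n_cells)]
    return ExpressionMatrix(values, genes, cells)


def generate_triplets(drugs: dict[str, str], expression: ExpressionMatrix,
                      rule: PlantedRule, n_triplets: int, seed: int
                      ) -> list[TripletSample]:
    """Sample (A ≠ B, cell) triplets and plant Bernoulli labels via the rule."""
    if len(drugs) < 2:
        raise ValueError("need at least two drugs to form pairs")
    rng = np.random.default_rng(seed)
    drug_ids = list(drugs)
    arom = {d: smiles_to_graph(s).aromatic_fraction for d, s in drugs.items()}
    subset = min(rule.gene_subset, len(expression.gene_ids))
    cell_feat = {c: float(expression.values[:subset, j].mean())
                 for j, c in enumerate(expression.cell_ids)}

    pair_idx = np.array([
        rng.choice(len(drug_ids), size=2, replace=False) for _ in range(n_triplets)
    ])
    cells = rng.choice(expression.cell_ids, size=n_triplets)
    a_ids = [drug_ids[i] for i in pair_idx[:, 0]]
    b_ids = [drug_ids[i] for i in pair_idx[:, 1]]
    link = rule.signal_strength * rule.bayes_scores(
        [arom[d] for d in a_ids], [arom[d] for d in b_ids],
        [cell_feat[c] for c in cells])
    link = link + rng.normal(0.0, rule.noise_sd, size=n_triplets)
    p = expit(link)
    labels = (rng.random(n_triplets) < p).astype(int)
    return [
        TripletSample(a, b, str(c), int(y))
        for a, b, c, y in zip(a_ids, b_ids, cells, labels)
    ]


@dataclass
class SyntheticDataset:
    """A complete generated study: drug table, expression, labeled triplets."""

    drugs: dict[str, str]
    expression: ExpressionMatrix
    triplets: list[TripletSample]
    config: SyntheticConfig = field(default_factory=SyntheticConfig)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """One call producing all three inputs, deterministically from the seed."""
    cfg = config or SyntheticConfig()
    drugs = generate_drug_library(cfg.n_drugs, cfg.seed)
    expression = generate_expression(cfg.n_cells, cfg.n_genes, cfg.seed + 1)
    rule = PlantedRule(cfg.signal_strength, cfg.noise_sd)
    triplets = generate_triplets(drugs, expression, rule,
                                 cfg.n_triplets, cfg.seed + 2)
    return SyntheticDataset(drugs, expression, triplets, cfg)
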