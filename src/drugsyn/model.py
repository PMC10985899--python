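"""The synergy classifier as a statsmodels-style model/results pair.

:class:`SynergyModel` is constructed from data — labeled drug-pair/cell
triplets, a drug SMILES table, and a cell-line expression matrix — plus a
:class:`ModelConfig`. ``fit()`` trains the network (GAT drug encoder →
cross-drug attention aggregation → tanh cell MLP → gated fusion → softmax
head, optimized with the dual-pass consistency loss) and returns a
:class:`SynergyResults` carrying per-fold evaluation reports, the training
history, and prediction/interpretation methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .aggregate import AAGAMParams, aggregate_pair
from .autodiff import Adam, SGD, Tensor, concat, gather
from .cell import CellMLPParams, ExpressionMatrix, encode_cell_batch, select_genes
from .chem import FEATURE_DIM, smiles_to_graph
from .encoder import DrugEncoder, pad_graphs
from .evaluate import (EvalReport, TripletSample, augment_order, compute_metrics,
                       order_sensitivity, split_dataset, swap_order)
from .fusion import MFICParams, mfic_stack
from .loss import LossConfig, PredictionHead, dual_pass_loss

__all__ = ["ModelConfig", "SynergyModel", "SynergyResults", "PRESETS"]


@dataclass
class ModelConfig:
    """Hyperparameters of the full architecture and trainer.

    Defaults: 64-dimensional GAT layers, batch size 128, learning rate
    1e-4, dropout 0.1, Adam; depths and head counts are conventions of the
    architecture family and everything is configurable.
    """

    # drug encoder
    gat_hidden: int = 64
    gat_heads: int = 4
    gat_depth: int = 2
    negative_slope: float = 0.2
    # cell encoder
    cell_hidden: tuple[int, ...] = (256,)
    cell_bias: bool = False
    log_transform: bool = False  # log2(x+1) before the MLP (for TPM inputs)
    # aggregation / fusion
    aagam_tied: bool = True
    mfic_depth: int = 2
    mfic_gate_bias: float = -1.0
    mfic_identity_carry: bool = False
    head_hidden: int = 64
    # trainer
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 128
    dropout: float = 0.1
    max_epochs: int = 60
    early_stop_patience: int = 5
    # loss
    kl_weight: float = 1.0
    learnable_alpha: bool = False
    epsilon: float = 1e-12

    def __post_init__(self):
        self.cell_hidden = tuple(self.cell_hidden)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


#: Named hyperparameter presets: the conservative default rate and the
#: faster rate that performs best at desk scale.
PRESETS: dict[str, dict] = {
    "base": {"learning_rate": 1e-4},
    "tuned": {"learning_rate": 1e-3},
}


class _Network:
    """All learnable components plus the frozen data tensors."""

    def __init__(self, cfg: ModelConfig, n_panel_genes: int, seed: int):
        rng = np.random.default_rng(seed)
        self.encoder = DrugEncoder(FEATURE_DIM, cfg.gat_hidden, cfg.gat_heads,
                                   cfg.gat_depth, cfg.negative_slope, rng)
        dim = self.encoder.out_dim
        self.aagam = AAGAMParams(dim, tied=cfg.aagam_tied, rng=rng)
        self.cell_mlp = CellMLPParams(n_panel_genes, cfg.cell_hidden, dim,
                                      use_bias=cfg.cell_bias, rng=rng)
        fused_dim = 3 * dim
        self.mfic = MFICParams(fused_dim, cfg.mfic_depth,
                               gate_bias_init=cfg.mfic_gate_bias,
                               identity_carry=cfg.mfic_identity_carry, rng=rng)
        self.head = PredictionHead(fused_dim, cfg.head_hidden, rng)
        self.alpha_raw = (Tensor(np.array(np.log(np.expm1(cfg.kl_weight) + 1e-12)),
                                 requires_grad=True)
                          if cfg.learnable_alpha else None)

    def parameters(self) -> list[Tensor]:
        params = (self.encoder.parameters() + self.aagam.parameters()
                  + self.cell_mlp.parameters() + self.mfic.parameters()
                  + self.head.parameters())
        if self.alpha_raw is not None:
            params.append(self.alpha_raw)
        return params

    def alpha(self) -> Tensor | None:
        return self.alpha_raw.softplus() if self.alpha_raw is not None else None

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def restore(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


class SynergyModel:
    """Drug-combination synergy classifier bound to a dataset.

    Parameters
    ----------
    triplets : labeled (drug A, drug B, cell line) samples.
    drug_smiles : mapping drug id → SMILES; every referenced drug must parse.
    expression : genes × cell-lines matrix covering all referenced cells.
    gene_panel : optional gene-id list restricting the expression rows
        (applied in panel order); by default all rows are used.
    config : architecture and trainer settings.
    """

    def __init__(self, triplets: list[TripletSample], drug_smiles: dict[str, str],
                 expression: ExpressionMatrix, *, gene_panel: list[str] | None = None,
                 config: ModelConfig | None = None):
        if not triplets:
            raise ValueError("no training triplets supplied")
        self.config = config or ModelConfig()
        self.triplets = list(triplets)
        if gene_panel is not None:
            expression = select_genes(expression, gene_panel)
        self.expression = expression
        missing_drugs = ({s.drug_a for s in triplets} | {s.drug_b for s in triplets}) \
            - set(drug_smiles)
        if missing_drugs:
            raise ValueError(f"triplets reference unknown drugs: {sorted(missing_drugs)}")
        missing_cells = {s.cell for s in triplets} - set(expression.cell_ids)
        if missing_cells:
            raise ValueError(f"triplets reference unknown cells: {sorted(missing_cells)}")

        self.drug_ids = sorted(drug_smiles)
        self.graphs = {d: smiles_to_graph(drug_smiles[d]) for d in self.drug_ids}
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._feats, self._adj, self._mask = pad_graphs(
            [self.graphs[d] for d in self.drug_ids])
        profiles = expression.values.T  # [cells, genes]
        if self.config.log_transform:
            profiles = np.log2(profiles + 1.0)
        self._profiles = profiles
        self._cell_index = {c: j for j, c in enumerate(expression.cell_ids)}
        self.network: _Network | None = None

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df, drug_smiles: dict[str, str],
                       expression: ExpressionMatrix, **kw) -> "SynergyModel":
        """Build from a DataFrame with columns drug_a, drug_b, cell_line and
        either ``label`` or ``loewe_score`` (routed through the Loewe rule)."""
        from .io import triplets_from_frame

        return cls(triplets_from_frame(df), drug_smiles, expression, **kw)

    # -- forward pass ---------------------------------------------------------
    def _forward(self, samples: list[TripletSample], *, training: bool = False,
                 rng: np.random.Generator | None = None,
                 return_scores: bool = False):
        cfg = self.config
        net = self.network
        dropout = cfg.dropout if training else 0.0
        e_all = net.encoder.encode_batch(self._feats, self._adj, self._mask,
                                         dropout=dropout, rng=rng)
        ia = np.array([self._drug_index[s.drug_a] for s in samples])
        ib = np.array([self._drug_index[s.drug_b] for s in samples])
        ic = np.array([self._cell_index[s.cell] for s in samples])
        e_a, e_b = gather(e_all, ia), gather(e_all, ib)
        m_a, m_b = self._mask[ia], self._mask[ib]
        g_x, g_y, s_a, s_b = aggregate_pair(e_a, e_b, m_a, m_b, net.aagam)
        v = encode_cell_batch(Tensor(self._profiles[ic]), net.cell_mlp,
                              dropout=dropout, rng=rng)
        fused = concat([g_x, g_y, v], axis=-1)
        fused = mfic_stack(fused, net.mfic)
        if training and dropout > 0 and rng is not None:
            fused = fused.dropout(dropout, rng)
        probs = net.head.probabilities(fused, dropout=dropout, rng=rng)
        if return_scores:
            return probs, (s_a, s_b, m_a, m_b)
        return probs

    def _predict_probs(self, samples: list[TripletSample]) -> np.ndarray:
        """P(synergistic) per sample, evaluation mode (no dropout)."""
        out = []
        for start in range(0, len(samples), 512):
            probs = self._forward(samples[start:start + 512])
            out.append(probs.data[:, 1])
        return np.concatenate(out)

    # -- training -------------------------------------------------------------
    def _train_once(self, fit_samples: list[TripletSample],
                    val_samples: list[TripletSample], seed: int,
                    verbose: bool = False) -> dict:
        cfg = self.config
        loss_cfg = LossConfig(cfg.kl_weight, cfg.learnable_alpha, cfg.epsilon)
        rng = np.random.default_rng(seed)
        opt_cls = Adam if cfg.optimizer == "adam" else SGD
        opt = opt_cls(self.network.parameters(), lr=cfg.learning_rate)
        labels_all = np.array([s.label for s in fit_samples])
        history: list[dict] = []
        best_auroc, best_state, stale = -np.inf, None, 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(fit_samples))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = [fit_samples[i] for i in idx]
                opt.zero_grad()
                p1 = self._forward(batch, training=True, rng=rng)
                p2 = self._forward(batch, training=True, rng=rng)
                loss = dual_pass_loss(p1, p2, labels_all[idx], loss_cfg,
                                      self.network.alpha())
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}")
                loss.backward()
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
            entry = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
            if val_samples:
                val_scores = self._predict_probs(val_samples)
                val_labels = np.array([s.label for s in val_samples])
                report = compute_metrics(val_scores, val_labels)
                entry["val_auroc"] = report.auroc
                if report.auroc > best_auroc:
                    best_auroc, stale = report.auroc, 0
                    best_state = self.network.snapshot()
                else:
                    stale += 1
            history.append(entry)
            if verbose:
                print(f"  epoch {epoch:3d}  loss {entry['loss']:.4f}"
                      + (f"  val AUROC {entry.get('val_auroc', float('nan')):.4f}"
                         if val_samples else ""))
            if val_samples and stale > cfg.early_stop_patience:
                break
        if best_state is not None:
            self.network.restore(best_state)
        return {"history": history, "best_val_auroc": best_auroc}

    def fit(self, *, seed: int = 0, cv: bool = False, augment: bool = False,
            test_fraction: float = 0.1, val_fraction: float = 0.1,
            verbose: bool = False) -> "SynergyResults":
        """Train the network and return a results object.

        ``cv=True`` runs the five-fold cross-validation protocol on the 90%
        training portion (each fold trained from scratch with early stopping
        on its validation AUROC) and keeps the best fold's checkpoint;
        ``cv=False`` trains a single model with an internal validation split.
        ``augment=True`` adds the order-swapped twin of every training
        sample.
        """
        train, test, folds = split_dataset(self.triplets, seed,
                                           test_fraction=test_fraction)
        fold_reports: list[EvalReport] = []
        histories: list[dict] = []
        if cv:
            best = (-np.inf, None)
            for k, (fit_idx, val_idx) in enumerate(folds):
                self.network = _Network(self.config, self._profiles.shape[1],
                                        seed + 1000 * (k + 1))
                fit_samples = [train[i] for i in fit_idx]
                val_samples = [train[i] for i in val_idx]
                if augment:
                    fit_samples = augment_order(fit_samples)
                if verbose:
                    print(f"fold {k + 1}/{len(folds)}")
                out = self._train_once(fit_samples, val_samples, seed + k, verbose)
                histories.append(out["history"])
                scores = self._predict_probs(val_samples)
                labels = np.array([s.label for s in val_samples])
                report = compute_metrics(scores, labels)
                fold_reports.append(report)
                if report.auroc > best[0]:
                    best = (report.auroc, self.network.snapshot())
            self.network = _Network(self.config, self._profiles.shape[1], seed)
            self.network.restore(best[1])
        else:
            self.network = _Network(self.config, self._profiles.shape[1], seed)
            rng = np.random.default_rng(seed)
            n_val = max(2, int(round(val_fraction * len(train))))
            perm = rng.permutation(len(train))
            val_samples = [train[i] for i in perm[:n_val]]
            fit_samples = [train[i] for i in perm[n_val:]]
            if augment:
                fit_samples = augment_order(fit_samples)
            out = self._train_once(fit_samples, val_samples, seed, verbose)
            histories.append(out["history"])
            scores = self._predict_probs(val_samples)
            labels = np.array([s.label for s in val_samples])
            fold_reports.append(compute_metrics(scores, labels))

        test_scores = self._predict_probs(test)
        test_labels = np.array([s.label for s in test])
        test_report = compute_metrics(test_scores, test_labels)
        train_scores = self._predict_probs(train)
        train_labels = np.array([s.label for s in train])
        train_report = compute_metrics(train_scores, train_labels)
        return SynergyResults(self, fold_reports, test_report, train_report,
                              histories, seed=seed, cv=cv, augment=augment,
                              train=train, test=test)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Serialize config + fitted parameters (NumPy ``.npz`` container)."""
        if self.network is None:
            raise RuntimeError("model is not fitted; nothing to save")
        import json

        arrays = {f"param_{i}": p.data for i, p in
                  enumerate(self.network.parameters())}
        meta = json.dumps({"config": asdict(self.config),
                           "n_panel_genes": int(self._profiles.shape[1])})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    def load(self, path, seed: int = 0) -> None:
        """Restore parameters saved by :meth:`save` into this model's
        network (architecture is rebuilt from the stored config)."""
        import json

        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            cfg = dict(meta["config"])
            cfg["cell_hidden"] = tuple(cfg["cell_hidden"])
            self.config = ModelConfig(**cfg)
            self.network = _Network(self.config, meta["n_panel_genes"], seed)
            params = self.network.parameters()
            self.network.restore([archive[f"param_{i}"]
                                  for i in range(len(params))])

    # -- interpretation -------------------------------------------------------
    def attention_scores(self, sample: TripletSample
                         ) -> tuple[np.ndarray, np.ndarray]:
        """Per-atom importance (S_A, S_B) for one triplet; each sums to 1."""
        if self.network is None:
            raise RuntimeError("model is not fitted")
        _, (s_a, s_b, m_a, m_b) = self._forward([sample], return_scores=True)
        n_a = self.graphs[sample.drug_a].num_atoms
        n_b = self.graphs[sample.drug_b].num_atoms
        return s_a.data[0, :n_a].copy(), s_b.data[0, :n_b].copy()


@dataclass
class SynergyResults:
    """Estimates and diagnostics from a fitted :class:`SynergyModel`."""

    model: SynergyModel
    fold_reports: list[EvalReport]
    test_report: EvalReport
    train_report: EvalReport
    histories: list[dict]
    seed: int
    cv: bool
    augment: bool
    train: list[TripletSample] = field(default_factory=list, repr=False)
    test: list[TripletSample] = field(default_factory=list, repr=False)

    # -- prediction -----------------------------------------------------------
    def predict(self, samples: list[TripletSample] | None = None) -> np.ndarray:
        """P(synergistic) for the given (default: held-out test) samples."""
        return self.model._predict_probs(samples if samples is not None else self.test)

    def order_swap_correlation(self, samples: list[TripletSample] | None = None
                               ) -> tuple[float, np.ndarray]:
        """Pearson r between predictions under (A,B,c) and (B,A,c) orders."""
        samples = samples if samples is not None else self.test
        return order_sensitivity(self.model._predict_probs(samples),
                                 self.model._predict_probs(swap_order(samples)))

    # -- reporting ------------------------------------------------------------
    def fold_mean_std(self) -> dict[str, tuple[float, float]]:
        """Per-metric mean ± std over folds (Table-style aggregation)."""
        keys = ["auroc", "aupr", "acc", "bacc", "prec", "tpr", "tnr", "kappa"]
        out = {}
        for k in keys:
            vals = np.array([getattr(r, k) for r in self.fold_reports])
            out[k] = (float(vals.mean()), float(vals.std()))
        return out

    def summary(self) -> str:
        """A plain-text summary table of the fit."""
        cfg = self.model.config
        lines = [
            "Drug-combination synergy classifier",
            "=" * 56,
            f"samples: {len(self.train)} train / {len(self.test)} test"
            f"   drugs: {len(self.model.drug_ids)}"
            f"   cells: {len(self.model._cell_index)}",
            f"protocol: {'5-fold CV' if self.cv else 'single fit'}"
            f"{' + order augmentation' if self.augment else ''}   seed: {self.seed}",
            f"optimizer: {cfg.optimizer}  lr: {cfg.learning_rate:g}"
            f"  batch: {cfg.batch_size}  dropout: {cfg.dropout:g}"
            f"  KL weight: {cfg.kl_weight:g}",
            "-" * 56,
            f"{'metric':<10}{'fold mean':>12}{'fold std':>12}{'test':>12}",
        ]
        agg = self.fold_mean_std()
        for k in ["auroc", "aupr", "acc", "bacc", "prec", "tpr", "tnr", "kappa"]:
            m, s = agg[k]
            lines.append(f"{k:<10}{m:>12.3f}{s:>12.3f}"
                         f"{getattr(self.test_report, k):>12.3f}")
        lines.append("-" * 56)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cv": self.cv,
            "augment": self.augment,
            "config": asdict(self.model.config),
            "fold_reports": [r.to_dict() for r in self.fold_reports],
            "test_report": self.test_report.to_dict(),
            "train_report": self.train_report.to_dict(),
        }
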