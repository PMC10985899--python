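# drugsyn

Anti-cancer drug combinations can be markedly more effective than single
agents, but screening every pair across every cell line is infeasible.
`drugsyn` predicts, for a triplet *(drug A, drug B, cell line)*, whether the
combination acts **synergistically** or **antagonistically**, and reports
which chemical substructures of each drug drive the call. It is aimed at
computational chemists and drug-discovery researchers who have combination
screens (Loewe-additivity synergy scores), drug SMILES, and cell-line
expression profiles, and want a trainable, interpretable classifier.

## Model

Drugs enter as SMILES and become molecular graphs (heavy atoms = nodes,
bonds = edges) with five atom descriptors: element symbol, heavy-atom
degree, implicit valence, attached hydrogens, aromaticity.

1. **Graph-attention encoder.** Per layer and head,
   `α_ij = softmax_j LeakyReLU(aᵀ[W h_i ‖ W h_j])` over `j ∈ N(i) ∪ {i}`,
   and `h'_i = σ(Σ_j α_ij W h_j)` with heads concatenated (hidden) or
   averaged (final). Defaults: 2 layers, 64-dim heads, 4 heads.
2. **Cross-drug attention aggregation.** Each atom of drug A is scored
   against all atoms of drug B:
   `S_A = softmax_i Σ_j tanh((E_A W_k)(E_B W_q)ᵀ)_{ij}`, then
   `g_x = Σ_i S_{A,i} (E_A W_v)_i` and
   `G_x = norm(mean_i(E_A) + g_x)` (layer normalization). `S_A` is the
   per-atom interpretability signal.
3. **Cell-line encoder.** Expression is TPM-normalized, restricted to a
   gene panel (default size 954), and embedded by a bias-free tanh MLP
   `v = tanh(… tanh(c W⁰) … W^{q_c})`.
4. **Gated fusion.** On `F = [G_x ‖ G_y ‖ v]`, stacked highway-style layers
   `y = g ⊙ relu(W F) + (1 − g) ⊙ Q F` with `g = sigmoid(G F)`.
5. **Dual-pass consistency loss.** Every training sample is forwarded twice
   with independent dropout; the loss is
   `L = ½[CE(ŷ₁) + CE(ŷ₂) + α(KL(ŷ₁‖ŷ₂) + KL(ŷ₂‖ŷ₁))]`, optimized with
   Adam (lr 1e-4 default; a `tuned` 1e-3 preset ships too).

Labels derive from Loewe synergy scores: `> 10` synergistic, `< 0`
antagonistic, `[0, 10]` discarded as a noise dead zone. Evaluation reports
AUROC, AUPR, ACC, BACC, PREC, TPR, TNR and Cohen's κ under a stratified
90/10 split with optional five-fold cross-validation, plus an order-swap
(Pearson r) robustness analysis. The whole network, including the
graph-attention layers and a compact reverse-mode autodiff core, is
implemented in NumPy — no deep-learning framework required.

## Worked example

```python
from drugsyn import synthetic, SynergyModel, ModelConfig

data = synthetic.generate_dataset(synthetic.SyntheticConfig(seed=42))
model = SynergyModel(data.triplets, data.drugs, data.expression,
                     config=ModelConfig(learning_rate=1e-3, max_epochs=40))
results = model.fit(seed=42)
print(results.summary())
```

```
Drug-combination synergy classifier
========================================================
samples: 900 train / 100 test   drugs: 30   cells: 20
protocol: single fit   seed: 42
optimizer: adam  lr: 0.001  batch: 128  dropout: 0.1  KL weight: 1
--------------------------------------------------------
metric       fold mean    fold std        test
auroc            0.949       0.000       0.939
aupr             0.948       0.000       0.938
acc              0.867       0.000       0.870
...
kappa            0.733       0.000       0.740
```

The synthetic study plants a known rule (aromaticity of both drugs plus a
cell expression feature, through a noisy logistic link), so held-out AUROC
≈ 0.94 means the model recovered the planted signal from raw SMILES and
expression alone. Per-atom attention localizes it:

```python
sample = results.test[0]
print(results.predict([sample])[0])        # 0.964  (true label: 1)
model.attention_scores(sample)             # per-atom importances, sum to 1
# bromobenzene: Br0=0.00, C1=0.01, C2=0.08, C3=0.24, C4=0.34, C5=0.24, C6=0.08
```

The same pipeline is scriptable from the shell:

```sh
drugsyn simulate --seed 7 --out data/
drugsyn train --triplets data/triplets.csv --drugs data/drugs.csv \
        --expression data/expression.csv --out run/
drugsyn explain --triplets data/triplets.csv --drugs data/drugs.csv \
        --expression data/expression.csv --model run/checkpoint.npz \
        --out run/attention.csv
```

For real screens, point `--triplets` at a table with `loewe_score` (the
Loewe rule labels it) and `--expression` at a TPM matrix with a
`--panel` gene list.

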