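# Methods

## Problem and model

The package classifies drug-pair/cell-line triplets as synergistic or
antagonistic. Synergy ground truth comes from Loewe-additivity scores of
dose–response matrices: the Loewe model predicts the effect of a
combination if the two drugs acted additively, and the signed deviation
from that prediction quantifies synergy (> 0) or antagonism (< 0). Because
scores near zero are dominated by assay noise, labeling uses a dead zone:
score > 10 → synergistic (1), score < 0 → antagonistic (0), scores in
[0, 10] are discarded.

The predictor is a multi-source neural architecture:

* **Molecular graphs.** SMILES are parsed with RDKit; heavy atoms are
  nodes, bonds undirected edges, hydrogens implicit. Atom features are
  fixed-width one-hot blocks — element over a 10-symbol vocabulary
  (C, N, O, S, F, Cl, Br, I, P, B) plus an "other" slot; heavy-atom
  degree, implicit valence and attached-H count each capped at 5 with an
  overflow bucket; one aromaticity bit — 33 columns total. One-hot blocks
  keep inputs bounded and match common cheminformatics featurizers; counts
  above 5 are chemically rare, so the overflow bucket loses almost
  nothing. Aromaticity uses the parser's aromaticity perception rather
  than strict benzene-ring detection, the standard proxy.

* **Graph-attention encoder.** Masked neighborhood softmax attention with
  self-loops (without them the softmax is undefined for isolated atoms and
  a single-atom drug such as methane would have no neighborhood). The
  attention logit is LeakyReLU-rectified (slope 0.2) before normalization.
  Hidden layers use ELU and concatenate heads; the final layer averages
  heads with identity activation. Defaults: depth 2, head width 64,
  4 heads — so node embeddings are 64-dimensional. Depth and head count
  are conventions of this architecture family; only the 64-dim layer width
  is an externally fixed choice.

* **Cross-drug aggregation.** Scores each atom of one drug against all
  atoms of the partner (tanh of the key/query inner-product matrix, summed
  over partner atoms, softmax over own atoms), pools value-projected atoms
  by those scores, adds the unweighted atom mean as a residual, and layer-
  normalizes (no learnable affine). The "weighted summation" reading of
  the score/value product is forced by dimensional analysis: an
  elementwise product would not produce a graph-level vector. Key/value
  projections belong to the self drug and the query projection to the
  partner; one parameter set is shared between the A→B and B→A directions
  (tying halves the parameters and empirically aids order robustness;
  untied is a config flag).

* **Cell-line encoder.** TPM normalization (counts/length rates scaled to
  10⁶ per library), restriction to a gene panel supplied as a file
  (default panel width 954, the landmark-style reduced space; the
  LINCS/CCLE/GENCODE curation that produces such panels requires versioned
  external databases and is out of scope), then a bias-free tanh MLP
  954 → 256 → 64. Biases are off by default to match the weights-only
  formulation; a `log2(TPM+1)` transform is available (off by default)
  because raw TPM spans orders of magnitude and saturates tanh.

* **Gated fusion (highway-style).** On the concatenation
  [G_x ‖ G_y ‖ v] (width 192), each layer blends a relu-affine branch and
  a linear-affine branch through a sigmoid gate with learnable affine
  parameters. Gate bias initializes at −1 so early training favors the
  carry path. Depth defaults to 2. A parameter-free gate (sigmoid of the
  input itself) and an identity carry are available for ablations.

* **Head and loss.** A 2-layer MLP produces two logits and a softmax.
  Training forwards each batch twice with independent dropout masks and
  minimizes the mean of both cross-entropies plus α times the symmetric KL
  divergence between the two predictive distributions (consistency
  regularization against dropout noise). α defaults to a fixed 1.0; a
  softplus-parameterized learnable α is a flag. Cross-entropy acts on the
  synergy-class probability, which for a two-class softmax is identical to
  categorical cross-entropy. Logs are clamped at ε = 1e-12.

## Training protocol

Stratified 90/10 train/test split; optional five-fold stratified
cross-validation of the training portion (each fold trained from scratch,
early-stopped on fold-validation AUROC, best checkpoint restored).
Stratification protects small runs from degenerate single-class folds and
is disclosed here as a deliberate choice. Optimizer is Adam (lr 1e-4
default, batch 128, dropout 0.1); plain SGD is a config option. Two
learning-rate presets ship — `base` (1e-4) and `tuned` (1e-3); the
desk-scale experiments in this repository use the `tuned` rate with max 40
epochs and patience 6, which converges on the synthetic benchmark in well
under a minute. Order augmentation optionally adds the (B, A, cell) twin of
every training sample. Confusion-based metrics threshold at 0.5; AUROC
uses midrank tie handling; κ is computed from the confusion marginals.

The entire network runs on a compact reverse-mode autodiff core over
NumPy float64 arrays. Graphs are padded per batch with boolean masks;
padded rows keep a diagonal self-loop so softmaxes stay defined and are
zeroed afterwards. Gradient correctness is tested against central finite
differences, and the attention layers against dense brute-force oracles.

## Synthetic benchmark

`drugsyn.synthetic` generates the full study: drugs sampled without
replacement from a curated pool of 36 small valid SMILES (aspirin,
caffeine, benzene, heterocycles, aliphatics — chosen to spread the
aromatic fraction over [0, 1]); cell profiles as i.i.d. standard normals
over a 954-gene panel (already normalized-scale, so the TPM path is
exercised separately); labels planted through
`Bernoulli(sigmoid(s·(z(arom_A) + z(arom_B) + z(cell_mean)) + ε))` with
signal strength s = 3, noise ε ~ N(0, 0.5), and the cell feature the mean
over the first 50 panel genes. Each feature is empirically standardized so
prevalence centers at 0.5. The rule deliberately couples a graph-visible
drug property with an expression feature, so recovering it requires both
branches and the fusion — not just one encoder. Defaults: 30 drugs, 20
cells, 1,000 triplets.

What the synthetic benchmark does **not** show: real combination screens
have correlated expression structure, drug-specific dose–response shapes,
class imbalance, and molecules far larger than the curated pool; planted
labels are a one-dimensional logistic rule, far simpler than biology.
Passing the benchmark demonstrates that the architecture, gradients,
training loop and data plumbing are correct and that the model can learn a
cross-source signal — not that it attains any particular accuracy on real
screens.

## Numerical choices and degenerate inputs

* Layer-norm ε 1e-5; all-zero readout input maps to the zero vector.
* Log clamp ε 1e-12 in losses; endpoint probabilities stay finite.
* Attention over an isolated atom is exactly 1 by construction.
* An all-zero expression library TPM-normalizes to zeros with a warning
  rather than an error.
* Dead-zone triplet rows are dropped at read time with a logged count.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; fits are bitwise reproducible per seed.

## Known limitations

Bond features (order, conjugation) are not used; stereochemistry and 3D
conformers are ignored. The checkpoint format is NumPy's `.npz` and is not
pinned across package versions. Training is CPU-bound NumPy — fine at the
tens-of-thousands-of-triplets scale, but a GPU framework would be needed
for much larger screens. AUROC/AUPR require both classes present in every
evaluated split.
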