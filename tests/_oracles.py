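"""Independent brute-force reference implementations used by the tests.

These deliberately use explicit Python loops and dense matrices so they
share no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

from drugsyn.chem import FEATURE_DIM, MolecularGraph


def dense_gat_head(feats: np.ndarray, adj: np.ndarray, weight: np.ndarray,
                   a_src: np.ndarray, a_dst: np.ndarray,
                   slope: float) -> tuple[np.ndarray, np.ndarray]:
    """One attention head: full masked logit matrix, row softmax.

    Returns (alpha [n,n], wh [n,k']). ``adj`` must already include
    self-loops.
    """
    wh = feats @ weight
    n = feats.shape[0]
    logits = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                z = float(a_src @ wh[i] + a_dst @ wh[j])
                logits[i, j] = z if z > 0 else slope * z
    alpha = np.zeros((n, n))
    for i in range(n):
        row = logits[i]
        m = row[np.isfinite(row)].max()
        e = np.where(np.isfinite(row), np.exp(row - m), 0.0)
        alpha[i] = e / e.sum()
    return alpha, wh


def dense_gat_layer(feats: np.ndarray, adj: np.ndarray, params) -> np.ndarray:
    """Full GAT layer via the dense oracle, matching the package's
    head-concatenation/averaging and activation conventions."""
    outs = []
    for m in range(params.num_heads):
        alpha, wh = dense_gat_head(feats, adj, params.weights[m].data,
                                   params.attn_src[m].data,
                                   params.attn_dst[m].data,
                                   params.negative_slope)
        outs.append(alpha @ wh)
    out = np.concatenate(outs, axis=-1) if params.concat_heads \
        else np.mean(outs, axis=0)
    if params.activation == "elu":
        out = np.where(out > 0, out, np.expm1(out))
    elif params.activation == "relu":
        out = np.maximum(out, 0)
    elif params.activation == "tanh":
        out = np.tanh(out)
    return out


def loop_cross_attention(e_self: np.ndarray, e_other: np.ndarray,
                         w_k: np.ndarray, w_q: np.ndarray) -> np.ndarray:
    """Nested-loop cross-attention scores for one drug pair."""
    n_self, n_other = e_self.shape[0], e_other.shape[0]
    summed = np.zeros(n_self)
    for i in range(n_self):
        for j in range(n_other):
            summed[i] += np.tanh(float((e_self[i] @ w_k) @ (e_other[j] @ w_q)))
    e = np.exp(summed - summed.max())
    return e / e.sum()


def auroc_by_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs concordance count with half credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_molecular_graph(rng: np.random.Generator, max_nodes: int = 8
                           ) -> MolecularGraph:
    """A random connected graph wrapped as a MolecularGraph with random
    feature rows (structure only; not chemically meaningful)."""
    n = int(rng.integers(1, max_nodes + 1))
    edges = []
    for j in range(1, n):  # random spanning tree keeps it connected
        i = int(rng.integers(0, j))
        edges.append((i, j))
    for _ in range(int(rng.integers(0, n))):
        i, j = sorted(rng.choice(n, 2, replace=False)) if n > 1 else (0, 0)
        if i != j and (i, j) not in edges:
            edges.append((int(i), int(j)))
    feats = rng.normal(size=(n, FEATURE_DIM))
    return MolecularGraph(smiles="", num_atoms=n, node_features=feats,
                          edges=sorted(edges),
                          atom_symbols=["C"] * n,
                          aromatic_flags=[False] * n)
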