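"""Graph-attention encoder: normalization, toy oracles, equivariance."""

import numpy as np
import pytest

from _oracles import dense_gat_layer, random_molecular_graph
from drugsyn.autodiff import Tensor
from drugsyn.chem import FEATURE_DIM, MolecularGraph
from drugsyn.encoder import (DrugEncoder, GATLayerParams, attention_coefficients,
                             encode_drug, gat_layer, pad_graphs)


def _toy_graph(n, edges, feats):
    return MolecularGraph(smiles="", num_atoms=n,
                          node_features=np.asarray(feats, dtype=float),
                          edges=edges, atom_symbols=["C"] * n,
                          aromatic_flags=[False] * n)


@pytest.fixture
def params(rng):
    return GATLayerParams(3, 4, num_heads=2, rng=rng)


def test_isolated_node_self_attention(params):
    g = _toy_graph(1, [], [[0.3, -1.2, 0.5]])
    alpha = attention_coefficients(g.node_features, g, params)
    np.testing.assert_allclose(alpha, np.ones((2, 1, 1)))


def test_identical_nodes_split_evenly(params):
    row = [0.4, 0.1, -0.7]
    g = _toy_graph(2, [(0, 1)], [row, row])
    alpha = attention_coefficients(g.node_features, g, params)
    np.testing.assert_allclose(alpha, 0.5, atol=1e-12)


def test_rows_sum_to_one_and_support_matches_neighborhood(rng, params):
    for _ in range(10):
        g = random_molecular_graph(rng)
        feats = rng.normal(size=(g.num_atoms, 3))
        alpha = attention_coefficients(feats, g, params)
        np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)
        adj = g.adjacency(self_loops=True) > 0
        assert np.all(alpha[:, ~adj] == 0.0)


def test_attention_matches_dense_oracle_on_path(rng, params):
    g = _toy_graph(3, [(0, 1), (1, 2)], rng.normal(size=(3, 3)))
    alpha = attention_coefficients(g.node_features, g, params)
    from _oracles import dense_gat_head
    adj = g.adjacency(self_loops=True) > 0
    for m in range(params.num_heads):
        ref, _ = dense_gat_head(g.node_features, adj, params.weights[m].data,
                                params.attn_src[m].data, params.attn_dst[m].data,
                                params.negative_slope)
        np.testing.assert_allclose(alpha[m], ref, atol=1e-6)


def test_zero_weights_give_activation_of_zero(rng):
    params = GATLayerParams(3, 4, num_heads=2, rng=rng)
    for w in params.weights:
        w.data[:] = 0.0
    g = _toy_graph(3, [(0, 1), (1, 2)], rng.normal(size=(3, 3)))
    out = gat_layer(g.node_features, g, params)
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_single_node_single_head_is_linear_map(rng):
    params = GATLayerParams(3, 4, num_heads=1, activation="identity", rng=rng)
    h = rng.normal(size=(1, 3))
    g = _toy_graph(1, [], h)
    out = gat_layer(h, g, params)
    np.testing.assert_allclose(out, h @ params.weights[0].data, atol=1e-12)


def test_layer_matches_dense_oracle(rng):
    for trial in range(5):
        g = random_molecular_graph(rng, max_nodes=6)
        params = GATLayerParams(FEATURE_DIM, 5, num_heads=3,
                                rng=np.random.default_rng(trial))
        out = gat_layer(g.node_features, g, params)
        ref = dense_gat_layer(g.node_features, g.adjacency() > 0, params)
        np.testing.assert_allclose(out, ref, atol=1e-6)


def test_depth_two_composes_oracle(rng):
    enc = DrugEncoder(FEATURE_DIM, hidden_dim=4, num_heads=2, depth=2, rng=rng)
    g = random_molecular_graph(rng, max_nodes=4)
    out = encode_drug(g, enc)
    adj = g.adjacency() > 0
    ref = dense_gat_layer(g.node_features, adj, enc.layers[0])
    ref = dense_gat_layer(ref, adj, enc.layers[1])
    np.testing.assert_allclose(out, ref, atol=1e-6)
    assert out.shape == (g.num_atoms, enc.out_dim)


def test_permutation_equivariance(rng):
    enc = DrugEncoder(FEATURE_DIM, hidden_dim=6, num_heads=2, depth=2, rng=rng)
    g = random_molecular_graph(rng, max_nodes=6)
    perm = rng.permutation(g.num_atoms)
    relabel = {old: new for new, old in enumerate(perm)}
    g_perm = MolecularGraph(
        smiles="", num_atoms=g.num_atoms,
        node_features=g.node_features[perm],
        edges=sorted(tuple(sorted((relabel[i], relabel[j]))) for i, j in g.edges),
        atom_symbols=["C"] * g.num_atoms, aromatic_flags=[False] * g.num_atoms)
    out, out_perm = encode_drug(g, enc), encode_drug(g_perm, enc)
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-8)


def test_shape_mismatch_raises(rng, params):
    feats = np.zeros((1, 2, 7))
    with pytest.raises(ValueError, match="incompatible"):
        from drugsyn.encoder import gat_layer_batch
        gat_layer_batch(Tensor(feats), np.ones((1, 2, 2), dtype=bool),
                        np.ones((1, 2), dtype=bool), params)


def test_padding_does_not_change_real_node_embeddings(rng):
    enc = DrugEncoder(FEATURE_DIM, hidden_dim=4, num_heads=2, depth=2, rng=rng)
    small = random_molecular_graph(rng, max_nodes=3)
    big = random_molecular_graph(rng, max_nodes=8)
    feats, adj, mask = pad_graphs([small, big])
    batched = enc.encode_batch(feats, adj, mask).data[0][:small.num_atoms]
    alone = enc.encode(small)
    np.testing.assert_allclose(batched, alone, atol=1e-10)


def test_empty_layer_stack_rejected():
    with pytest.raises(ValueError):
        DrugEncoder(FEATURE_DIM, depth=0)
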