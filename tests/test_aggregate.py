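"""Cross-drug attention aggregation: normalization, oracles, invariances."""

import numpy as np
import pytest

from _oracles import loop_cross_attention
from drugsyn.aggregate import (AAGAMParams, aggregate_pair, attention_pool,
                               cross_attention_scores, graph_readout, layer_norm)
from drugsyn.autodiff import Tensor


@pytest.fixture
def params(rng):
    return AAGAMParams(4, rng=rng)


def test_zero_embeddings_give_uniform_scores(params):
    scores = cross_attention_scores(np.zeros((5, 4)), np.zeros((3, 4)), params)
    np.testing.assert_allclose(scores, 0.2, atol=1e-12)


def test_single_atom_scores_one(params, rng):
    scores = cross_attention_scores(rng.normal(size=(1, 4)),
                                    rng.normal(size=(6, 4)), params)
    np.testing.assert_allclose(scores, [1.0])


def test_scores_match_nested_loop_oracle(rng):
    for trial in range(5):
        local = np.random.default_rng(trial)
        p = AAGAMParams(4, rng=local)
        e_self = local.normal(size=(2 + trial % 3, 4))
        e_other = local.normal(size=(3, 4))
        got = cross_attention_scores(e_self, e_other, p)
        ref = loop_cross_attention(e_self, e_other, p.key_proj.data,
                                   p.query_proj.data)
        np.testing.assert_allclose(got, ref, atol=1e-6)


def test_identity_projection_oracle(rng):
    p = AAGAMParams(4, rng=rng)
    p.key_proj.data = np.eye(4)
    p.query_proj.data = np.eye(4)
    e_self, e_other = rng.normal(size=(2, 4)), rng.normal(size=(3, 4))
    got = cross_attention_scores(e_self, e_other, p)
    ref = loop_cross_attention(e_self, e_other, np.eye(4), np.eye(4))
    np.testing.assert_allclose(got, ref, atol=1e-8)


def test_scores_positive_and_normalized(rng, params):
    e_self, e_other = rng.normal(size=(7, 4)), rng.normal(size=(4, 4))
    s = cross_attention_scores(e_self, e_other, params)
    assert np.all(s > 0)
    assert s.sum() == pytest.approx(1.0, abs=1e-6)


def test_pool_single_atom_returns_value_row(rng, params):
    e = rng.normal(size=(1, 4))
    np.testing.assert_allclose(attention_pool(e, np.array([1.0]), params),
                               (e @ params.value_proj.data)[0], atol=1e-12)


def test_pool_uniform_scores_is_mean(rng, params):
    e = rng.normal(size=(4, 4))
    got = attention_pool(e, np.full(4, 0.25), params)
    np.testing.assert_allclose(got, (e @ params.value_proj.data).mean(axis=0),
                               atol=1e-12)


def test_pool_weighted_sum_by_hand(rng, params):
    e = rng.normal(size=(3, 4))
    w = np.array([0.5, 0.3, 0.2])
    values = e @ params.value_proj.data
    ref = 0.5 * values[0] + 0.3 * values[1] + 0.2 * values[2]
    np.testing.assert_allclose(attention_pool(e, w, params), ref, atol=1e-12)


def test_readout_zero_input_is_zero():
    out = graph_readout(np.zeros((3, 4)), np.zeros(4))
    np.testing.assert_allclose(out, 0.0, atol=1e-12)


def test_readout_is_layer_normalized(rng):
    e, g = rng.normal(size=(3, 4)), rng.normal(size=4)
    out = graph_readout(e, g)
    pre = e.mean(axis=0) + g
    ref = (pre - pre.mean()) / np.sqrt(pre.var() + 1e-5)
    np.testing.assert_allclose(out, ref, atol=1e-10)
    assert out.mean() == pytest.approx(0.0, abs=1e-10)


def test_layer_norm_moments(rng):
    t = layer_norm(Tensor(rng.normal(size=(5, 16))))
    np.testing.assert_allclose(t.data.mean(axis=-1), 0.0, atol=1e-10)
    np.testing.assert_allclose(t.data.var(axis=-1), 1.0, atol=1e-3)


def test_aggregation_invariant_to_atom_relabeling(rng, params):
    e_a, e_b = rng.normal(size=(5, 4)), rng.normal(size=(3, 4))
    m = np.ones((1, 5), dtype=bool), np.ones((1, 3), dtype=bool)
    gx, gy, sa, _ = aggregate_pair(Tensor(e_a[None]), Tensor(e_b[None]),
                                   m[0], m[1], params)
    perm = rng.permutation(5)
    gx_p, gy_p, sa_p, _ = aggregate_pair(Tensor(e_a[perm][None]),
                                         Tensor(e_b[None]), m[0], m[1], params)
    np.testing.assert_allclose(gx_p.data, gx.data, atol=1e-8)
    np.testing.assert_allclose(gy_p.data, gy.data, atol=1e-8)
    np.testing.assert_allclose(sa_p.data[0], sa.data[0][perm], atol=1e-8)


def test_scores_depend_on_partner(rng, params):
    e_a = rng.normal(size=(4, 4))
    s1 = cross_attention_scores(e_a, rng.normal(size=(3, 4)), params)
    s2 = cross_attention_scores(e_a, rng.normal(size=(3, 4)), params)
    assert not np.allclose(s1, s2)


def test_width_mismatch_raises(rng, params):
    with pytest.raises(ValueError, match="width"):
        cross_attention_scores(rng.normal(size=(3, 5)),
                               rng.normal(size=(3, 4)), params)


def test_untied_parameters_differ_by_direction(rng):
    p = AAGAMParams(4, tied=False, rng=rng)
    assert p.key_proj is not p.key_proj_b
    assert len(p.parameters()) == 6
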