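"""Prediction head and the dual-pass consistency loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugsyn.autodiff import Tensor
from drugsyn.loss import (LossConfig, PredictionHead, cross_entropy,
                          dual_pass_loss, kl_divergence)


class TestHead:
    def test_zero_logits_give_half(self, rng):
        head = PredictionHead(4, 3, rng=rng)
        for p in head.parameters():
            p.data[:] = 0.0
        probs = head.probabilities(Tensor(rng.normal(size=(5, 4)))).data
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_softmax_closed_form(self):
        t = Tensor(np.array([[0.0, np.log(3.0)]]))
        probs = t.softmax(axis=-1).data[0]
        assert probs[1] == pytest.approx(0.75, abs=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        head = PredictionHead(4, 3, rng=rng)
        probs = head.probabilities(Tensor(rng.normal(size=(10, 4)))).data
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy(np.array([1.0]), np.array([1])).item() \
            == pytest.approx(0.0, abs=1e-9)

    def test_half_is_ln_two(self):
        for y in (0, 1):
            got = cross_entropy(np.array([0.5]), np.array([y])).item()
            assert got == pytest.approx(np.log(2.0), abs=1e-9)

    def test_confident_wrong_prediction(self):
        got = cross_entropy(np.array([0.9]), np.array([0])).item()
        assert got == pytest.approx(-np.log(0.1), abs=1e-9)

    def test_endpoints_finite_via_clamping(self):
        assert np.isfinite(cross_entropy(np.array([0.0]), np.array([1])).item())
        assert np.isfinite(cross_entropy(np.array([1.0]), np.array([0])).item())


class TestKL:
    def test_identical_distributions_zero(self):
        p = np.array([[0.3, 0.7]])
        assert kl_divergence(p, p).item() == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform_closed_form(self):
        got = kl_divergence(np.array([[1.0, 0.0]]),
                            np.array([[0.5, 0.5]]), eps=1e-300).item()
        assert got == pytest.approx(np.log(2.0), abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(1e-6, 1 - 1e-6), st.floats(1e-6, 1 - 1e-6))
    def test_nonnegative(self, a, b):
        p, q = np.array([[a, 1 - a]]), np.array([[b, 1 - b]])
        assert kl_divergence(p, q).item() >= -1e-12


class TestDualPass:
    def _probs(self, rng, n=6):
        p = rng.uniform(0.05, 0.95, size=n)
        return Tensor(np.column_stack([1 - p, p]))

    def test_identical_passes_reduce_to_cross_entropy(self, rng):
        probs = self._probs(rng)
        labels = rng.integers(0, 2, size=6)
        cfg = LossConfig(kl_weight=7.0)
        loss = dual_pass_loss(probs, probs, labels, cfg).item()
        ce = cross_entropy(probs.data[:, 1], labels).item()
        assert loss == pytest.approx(ce, abs=1e-9)

    def test_alpha_zero_averages_cross_entropies(self, rng):
        p1, p2 = self._probs(rng), self._probs(rng)
        labels = rng.integers(0, 2, size=6)
        loss = dual_pass_loss(p1, p2, labels, LossConfig(kl_weight=0.0)).item()
        ce1 = cross_entropy(p1.data[:, 1], labels).item()
        ce2 = cross_entropy(p2.data[:, 1], labels).item()
        assert loss == pytest.approx(0.5 * (ce1 + ce2), abs=1e-9)

    def test_symmetric_under_pass_swap(self, rng):
        p1, p2 = self._probs(rng), self._probs(rng)
        labels = rng.integers(0, 2, size=6)
        cfg = LossConfig(kl_weight=1.3)
        assert dual_pass_loss(p1, p2, labels, cfg).item() == pytest.approx(
            dual_pass_loss(p2, p1, labels, cfg).item(), abs=1e-12)

    def test_matches_hand_composition(self, rng):
        p1, p2 = self._probs(rng), self._probs(rng)
        labels = rng.integers(0, 2, size=6)
        cfg = LossConfig(kl_weight=2.0)
        ref = 0.5 * (cross_entropy(p1.data[:, 1], labels).item()
                     + cross_entropy(p2.data[:, 1], labels).item()
                     + 2.0 * (kl_divergence(p1.data, p2.data).item()
                              + kl_divergence(p2.data, p1.data).item()))
        assert dual_pass_loss(p1, p2, labels, cfg).item() \
            == pytest.approx(ref, abs=1e-9)

    def test_finite_for_extreme_probabilities(self):
        p1 = Tensor(np.array([[1.0, 0.0]]))
        p2 = Tensor(np.array([[0.0, 1.0]]))
        loss = dual_pass_loss(p1, p2, np.array([1]), LossConfig())
        assert np.isfinite(loss.item())


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(kl_weight=-0.1)
    with pytest.raises(ValueError):
        LossConfig(epsilon=0.0)
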