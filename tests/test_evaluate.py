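"""Labeling, splitting, augmentation, and classification metrics."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from _oracles import auroc_by_concordance
from drugsyn.evaluate import (ConfusionCounts, TripletSample, augment_order,
                              compute_metrics, label_by_loewe,
                              order_sensitivity, split_dataset, swap_order)


def _samples(n, prevalence=0.5, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = int(rng.random() < prevalence)
        out.append(TripletSample(f"d{i % 7}", f"e{i % 5}", f"c{i % 3}", label))
    return out


class TestLoeweLabeling:
    @pytest.mark.parametrize("score, expected", [
        (15.2, 1), (10.0001, 1), (-3.0, 0), (-0.0001, 0),
        (5.0, None), (0.0, None), (10.0, None),
    ])
    def test_threshold_rule(self, score, expected):
        assert label_by_loewe(score) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            label_by_loewe(float("nan"))


class TestSplit:
    def test_balanced_hundred_gives_ten_test_and_folds_of_eighteen(self):
        samples = _samples(100, seed=1)
        # force exact balance
        samples = [TripletSample(s.drug_a, s.drug_b, s.cell, i % 2)
                   for i, s in enumerate(samples)]
        train, test, folds = split_dataset(samples, seed=3)
        assert len(test) == 10 and len(train) == 90
        assert all(len(val) == 18 for _, val in folds)

    def test_deterministic_for_seed(self):
        samples = _samples(60)
        a = split_dataset(samples, seed=5)
        b = split_dataset(samples, seed=5)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_partition_is_disjoint_cover(self):
        samples = _samples(80)
        train, test, folds = split_dataset(samples, seed=2)
        from collections import Counter
        assert Counter(train + test) == Counter(samples)
        all_val = [i for _, val in folds for i in val]
        assert sorted(all_val) == list(range(len(train)))
        for fit, val in folds:
            assert set(fit).isdisjoint(val)
            assert sorted(fit + val) == list(range(len(train)))

    def test_stratification_keeps_prevalence(self):
        samples = _samples(100, prevalence=0.3, seed=4)
        train, test, folds = split_dataset(samples, seed=0)
        global_prev = np.mean([s.label for s in samples])
        for _, val in folds:
            fold_prev = np.mean([train[i].label for i in val])
            assert abs(fold_prev * len(val) - global_prev * len(val)) <= 1.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_samples(5), seed=0)


class TestAugment:
    def test_doubles_and_preserves_labels(self):
        samples = _samples(9)
        out = augment_order(samples)
        assert len(out) == 18
        for orig, twin in zip(samples, out[9:]):
            assert twin.drug_a == orig.drug_b and twin.drug_b == orig.drug_a
            assert twin.label == orig.label and twin.cell == orig.cell

    def test_swap_is_involution(self):
        samples = _samples(6)
        assert swap_order(swap_order(samples)) == samples


class TestMetrics:
    def _scores_for_confusion(self, tp, fp, tn, fn):
        labels = np.r_[np.ones(tp + fn), np.zeros(tn + fp)].astype(int)
        scores = np.r_[np.full(tp, 0.9), np.full(fn, 0.1),
                       np.full(tn, 0.1), np.full(fp, 0.9)]
        return scores, labels

    def test_worked_confusion_example(self):
        scores, labels = self._scores_for_confusion(40, 10, 40, 10)
        r = compute_metrics(scores, labels)
        assert r.acc == pytest.approx(0.8)
        assert r.tpr == pytest.approx(0.8)
        assert r.tnr == pytest.approx(0.8)
        assert r.bacc == pytest.approx(0.8)
        assert r.prec == pytest.approx(0.8)
        assert r.kappa == pytest.approx(0.6)

    def test_perfect_predictor(self):
        scores, labels = self._scores_for_confusion(50, 0, 50, 0)
        r = compute_metrics(scores, labels)
        for k in ("auroc", "aupr", "acc", "bacc", "prec", "tpr", "tnr", "kappa"):
            assert getattr(r, k) == pytest.approx(1.0)

    def test_constant_predictor_on_balanced_set(self):
        labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
        r = compute_metrics(np.full(100, 0.5), labels)
        assert r.acc == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.0)
        assert r.auroc == pytest.approx(0.5)

    def test_auroc_matches_concordance_oracle(self, rng):
        scores = np.round(rng.random(200), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=200)
        r = compute_metrics(scores, labels)
        assert r.auroc == pytest.approx(auroc_by_concordance(scores, labels),
                                        abs=1e-9)

    def test_bacc_identity_and_kappa_bounds_random_tables(self, rng):
        for _ in range(30):
            labels = rng.integers(0, 2, size=50)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.random(50)
            r = compute_metrics(scores, labels)
            assert r.bacc == pytest.approx((r.tpr + r.tnr) / 2, abs=1e-9)
            assert -1.0 <= r.kappa <= 1.0
            predicted = (scores >= 0.5).astype(int)
            assert r.kappa == pytest.approx(
                cohen_kappa_score(labels, predicted), abs=1e-9)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_confusion_counts_total(self, rng):
        labels = rng.integers(0, 2, 40)
        predicted = rng.integers(0, 2, 40)
        c = ConfusionCounts.from_predictions(labels, predicted)
        assert c.total == 40


class TestOrderSensitivity:
    def test_identical_predictions_perfectly_correlated(self):
        x = np.array([0.2, 0.8, 0.5])
        r, paired = order_sensitivity(x, x.copy())
        assert r == 1.0
        assert paired.shape == (3, 2)

    def test_known_correlation(self, rng):
        x = rng.random(100)
        y = x + rng.normal(0, 1e-3, 100)
        r, _ = order_sensitivity(x, y)
        assert r > 0.99

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            order_sensitivity(np.array([0.5]), np.array([0.5]))


def test_triplet_sample_validation():
    with pytest.raises(ValueError, match="pair"):
        TripletSample("a", "a", "c", 1)
    with pytest.raises(ValueError, match="label"):
        TripletSample("a", "b", "c", 3)
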