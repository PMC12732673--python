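"""Metric identities against brute-force counting oracles and reference
implementations of the agreement statistics."""

import numpy as np
import pytest

from deepblastoid import evaluation as ev
from deepblastoid.labels import N_CLASSES


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 4, 0])
        cm = ev.confusion_matrix(y, y)
        assert np.array_equal(np.diag(cm), np.bincount(y, minlength=5))
        assert cm.sum() == len(y)

    def test_swapped_pair(self):
        cm = ev.confusion_matrix(["A", "B"], ["B", "A"])
        assert cm[0, 1] == 1 and cm[1, 0] == 1 and np.trace(cm) == 0

    def test_matches_brute_force_counts(self, rng):
        y = rng.integers(0, 5, 200)
        p = rng.integers(0, 5, 200)
        cm = ev.confusion_matrix(y, p)
        for i in range(5):
            for j in range(5):
                assert cm[i, j] == int(np.sum((y == i) & (p == j)))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_matrix(["A", "X"], ["A", "A"])


class TestTopkAccuracy:
    def test_top5_exhaustive(self, rng):
        proba = rng.dirichlet(np.ones(5), 50)
        y = rng.integers(0, 5, 50)
        assert ev.topk_accuracy(y, proba, 5) == 1.0

    def test_second_ranked_counts_only_for_top2(self):
        proba = np.array([[0.1, 0.3, 0.4, 0.1, 0.1]])  # ranking C > B > ...
        assert ev.topk_accuracy(["B"], proba, 1) == 0.0
        assert ev.topk_accuracy(["B"], proba, 2) == 1.0

    def test_matches_sorting_oracle(self, rng):
        proba = rng.dirichlet(np.ones(5), 100)
        y = rng.integers(0, 5, 100)
        for k in range(1, 6):
            expected = np.mean(
                [yi in list(np.argsort(-p, kind="stable")[:k]) for yi, p in zip(y, proba)]
            )
            assert ev.topk_accuracy(y, proba, k) == pytest.approx(expected)

    def test_monotone_in_k(self, rng):
        proba = rng.dirichlet(np.ones(5), 80)
        y = rng.integers(0, 5, 80)
        accs = [ev.topk_accuracy(y, proba, k) for k in range(1, 6)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))

    def test_tie_breaks_to_lowest_index(self):
        proba = np.array([[0.5, 0.5, 0, 0, 0]])
        assert ev.topk_accuracy(["A"], proba, 1) == 1.0
        assert ev.topk_accuracy(["B"], proba, 1) == 0.0


class TestClassMetrics:
    def test_perfect_diagonal(self):
        cm = np.diag([4, 3, 2, 1, 5])
        m = ev.class_metrics(cm)
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0
        assert (m["per_class"][["precision", "recall", "specificity", "f1"]] == 1.0).all().all()

    def test_two_class_hand_count(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0], cm[0, 1], cm[1, 1] = 5, 5, 10
        m = ev.class_metrics(cm)["per_class"]
        assert m.loc["A", "recall"] == pytest.approx(0.5)
        assert m.loc["A", "precision"] == pytest.approx(1.0)
        assert m.loc["A", "f1"] == pytest.approx(2 / 3)

    def test_matches_one_vs_rest_oracle(self, rng):
        for _ in range(50):
            cm = rng.integers(0, 20, (5, 5))
            if cm.sum() == 0:
                continue
            m = ev.class_metrics(cm)["per_class"]
            total = cm.sum()
            for c in range(5):
                tp = cm[c, c]
                fp = cm[:, c].sum() - tp
                fn = cm[c, :].sum() - tp
                tn = total - tp - fp - fn
                assert tp + fp + fn + tn == total
                if tp + fp:
                    assert m.iloc[c]["precision"] == pytest.approx(tp / (tp + fp))
                else:
                    assert np.isnan(m.iloc[c]["precision"])
                if tn + fp:
                    assert m.iloc[c]["specificity"] == pytest.approx(tn / (tn + fp))

    def test_accuracy_is_trace_over_total(self, rng):
        cm = rng.integers(0, 30, (5, 5))
        assert ev.class_metrics(cm)["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())

    def test_undefined_metrics_are_nan_not_zero(self):
        cm = np.zeros((5, 5), dtype=int)
        cm[0, 0] = 10  # classes B..W never seen nor predicted
        m = ev.class_metrics(cm)["per_class"]
        assert np.isnan(m.loc["B", "precision"])
        assert np.isnan(m.loc["B", "recall"])
        assert ev.class_metrics(cm)["macro_f1"] == 1.0  # only defined classes averaged


class TestFleissKappa:
    def test_unanimous_is_one(self):
        table = [[c] * 3 for c in "ABCDW" for _ in range(2)]
        assert ev.fleiss_kappa(table) == pytest.approx(1.0)

    def test_complete_disagreement_balanced_marginals(self):
        # 2 items, 2 raters, both categories used equally: kappa = -1
        table = [["A", "B"], ["B", "A"]]
        assert ev.fleiss_kappa(table) == pytest.approx(-1.0)

    def test_matches_longhand_computation(self, rng):
        labels = rng.integers(0, 5, size=(20, 3))
        kappa = ev.fleiss_kappa(labels)
        # longhand: per-item pairwise agreement and pooled marginals
        n, r = labels.shape
        counts = np.array([[np.sum(row == c) for c in range(5)] for row in labels])
        p_item = (counts * (counts - 1)).sum(axis=1) / (r * (r - 1))
        p_bar = p_item.mean()
        p_cat = counts.sum(axis=0) / (n * r)
        p_e = (p_cat**2).sum()
        assert kappa == pytest.approx((p_bar - p_e) / (1 - p_e), abs=1e-12)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.inter_rater import aggregate_raters
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        labels = rng.integers(0, 5, size=(30, 4))
        counts, _ = aggregate_raters(labels)
        assert ev.fleiss_kappa(labels) == pytest.approx(sm_fleiss(counts), abs=1e-12)

    def test_single_category_everywhere_undefined(self):
        table = [["A", "A"], ["A", "A"]]
        assert np.isnan(ev.fleiss_kappa(table))

    def test_single_flip_reduces_agreement(self):
        table = np.zeros((10, 3), dtype=int)
        base = ev.fleiss_kappa(np.where(np.arange(10)[:, None] < 5, table, 1))
        flipped = np.where(np.arange(10)[:, None] < 5, table, 1)
        flipped[0, 0] = 2
        assert ev.fleiss_kappa(flipped) < base


class TestKrippendorffAlpha:
    def test_unanimous_is_one(self):
        table = [[c] * 4 for c in "ABW" for _ in range(3)]
        assert ev.krippendorff_alpha(table) == pytest.approx(1.0)

    def test_one_disagreement_between_zero_and_one(self):
        # several categories in use, one single disagreeing rating
        table = [[c, c] for c in "ABCDW" for _ in range(4)] + [["A", "B"]]
        alpha = ev.krippendorff_alpha(table)
        assert 0 < alpha < 1

    def test_matches_longhand_with_missing_cells(self, rng):
        labels = rng.integers(0, 5, size=(15, 3)).astype(float)
        mask = rng.random((15, 3)) < 0.2
        labels[mask] = np.nan
        alpha = ev.krippendorff_alpha(labels)
        # longhand coincidence-matrix computation
        coin = np.zeros((5, 5))
        for row in labels:
            vals = row[~np.isnan(row)].astype(int)
            m = len(vals)
            if m < 2:
                continue
            for i in range(m):
                for j in range(m):
                    if i != j:
                        coin[vals[i], vals[j]] += 1 / (m - 1)
        n = coin.sum()
        do = n - np.trace(coin)
        de = (n * n - (coin.sum(axis=1) ** 2).sum()) / (n - 1)
        assert alpha == pytest.approx(1 - do / de, abs=1e-12)

    def test_single_flip_reduces_alpha(self):
        table = np.array([[0, 0, 0]] * 5 + [[1, 1, 1]] * 5)
        base = ev.krippendorff_alpha(table)
        flipped = table.copy()
        flipped[0, 0] = 3
        assert ev.krippendorff_alpha(flipped) < base
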