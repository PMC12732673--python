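"""Training-harness contracts: augmentation statistics, loss arithmetic,
iteration bookkeeping, learnability and deterministic inference."""

import numpy as np
import pytest

from deepblastoid import classifier as clf
from deepblastoid import synthgen as sg
from deepblastoid.labels import encode_labels


@pytest.fixture(scope="module")
def small_train(balanced_tiles):
    images, _, codes, _ = balanced_tiles
    return images[:150], codes[:150]


class TestAugment:
    def test_disabled_is_identity(self):
        img = sg.render_microwell("A", seed=0, image_size=64)[0].astype(np.float32) / 65535
        cfg = clf.TrainConfig(hflip=False, vflip=False, jitter=False, scaling=False, erasing=False)
        out = clf.augment(img, cfg, seed=5)
        assert np.array_equal(out, img)

    def test_stated_probabilities_hold_empirically(self):
        """Jitter fires at ~40% and erasing at ~20% over many seeded draws."""
        img = np.full((64, 64), 0.5, dtype=np.float32)
        cfg = clf.TrainConfig(hflip=False, vflip=False, scaling=False)
        rng = np.random.default_rng(0)
        n = 10_000
        jit = er = 0
        for _ in range(n):
            _, ops = clf.augment(img, cfg, rng, return_ops=True)
            jit += ops.get("jitter", False)
            er += ops.get("erasing", False)
        assert abs(jit / n - 0.40) < 0.015
        assert abs(er / n - 0.20) < 0.015

    def test_scaling_factor_range(self):
        img = np.full((64, 64), 0.5, dtype=np.float32)
        cfg = clf.TrainConfig(hflip=False, vflip=False, jitter=False, erasing=False)
        rng = np.random.default_rng(1)
        factors = [clf.augment(img, cfg, rng, return_ops=True)[1]["scale_factor"] for _ in range(10_000)]
        assert min(factors) >= 0.8 and max(factors) <= 1.0

    def test_output_shape_preserved(self):
        img = sg.render_microwell("C", seed=1, image_size=64)[0].astype(np.float32) / 65535
        out = clf.augment(img, clf.TrainConfig(), seed=3)
        assert out.shape == img.shape


class TestCrossEntropy:
    def test_certainty_gives_zero(self):
        assert clf.cross_entropy([1, 0, 0, 0, 0], "A") == 0.0

    def test_uniform_vector(self):
        assert clf.cross_entropy([0.2] * 5, "C") == pytest.approx(-np.log(0.2), abs=1e-12)

    def test_half_probability(self):
        p = [0.5, 0.125, 0.125, 0.125, 0.125]
        assert clf.cross_entropy(p, "A") == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_probability_clamped(self):
        loss = clf.cross_entropy([0, 1, 0, 0, 0], "A")
        assert np.isfinite(loss) and loss > 20

    def test_invalid_vectors_rejected(self):
        with pytest.raises(ValueError):
            clf.cross_entropy([0.5, 0.5, 0.5, 0, 0], "A")
        with pytest.raises(ValueError):
            clf.cross_entropy([-0.1, 0.3, 0.3, 0.3, 0.2], "A")


class TestIterationArithmetic:
    @pytest.mark.parametrize(
        "n,bs,expected",
        [(1796, 62, 29), (500, 62, 9), (100, 100, 1), (101, 100, 2), (1, 1, 1)],
    )
    def test_iterations_per_epoch(self, n, bs, expected):
        assert clf.iterations_per_epoch(n, bs) == expected

    def test_cumulative_iterations_at_plateau_epoch(self):
        assert clf.cumulative_iterations(24, 1796, 62) == 696

    def test_training_log_length_matches_formula(self, small_train):
        X, y = small_train
        cfg = clf.TrainConfig(epochs=2, batch_size=64, input_size=64, seed=0)
        _, log = clf.train(X, y, cfg)
        assert log.iterations_per_epoch == 3  # ceil(150/64)
        assert log.iterations == 2 * 3


class TestTraining:
    def test_loss_decreases_on_learnable_data(self, small_train):
        X, y = small_train
        cfg = clf.TrainConfig(epochs=5, input_size=64, seed=0)
        _, log = clf.train(X, y, cfg)
        ipe = log.iterations_per_epoch
        first = np.mean(log.iter_loss[:ipe])
        last = np.mean(log.iter_loss[-ipe:])
        assert last < first

    def test_epochs_zero_gives_chance_level(self, balanced_tiles):
        images, _, codes, _ = balanced_tiles
        cfg = clf.TrainConfig(epochs=0, input_size=64, seed=0)
        est, log = clf.train(images[:200], codes[:200], cfg)
        assert log.iterations == 0
        acc = est.score(images[500:700], codes[500:700])
        assert abs(acc - 0.2) <= 0.08

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            clf.BlastoidClassifier().fit(np.zeros((0, 64, 64)), [])

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 64, 64), dtype=np.uint16)
        with pytest.raises(ValueError, match="2 classes"):
            clf.BlastoidClassifier(epochs=1).fit(X, ["A"] * 10)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            clf.BlastoidClassifier(backbone="resnet18").fit(
                np.zeros((4, 64, 64)), ["A", "B", "A", "B"]
            )


@pytest.fixture(scope="module")
def fitted(small_train):
    X, y = small_train
    cfg = clf.TrainConfig(epochs=3, input_size=64, seed=2)
    est, _ = clf.train(X, y, cfg)
    return est, X


class TestInference:
    def test_rows_are_probability_vectors(self, fitted):
        est, X = fitted
        proba = est.predict_proba(X[:20])
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_repeated_inference_bit_identical(self, fitted):
        est, X = fitted
        a = est.predict_proba(X[:10])
        b = est.predict_proba(X[:10])
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self, fitted):
        est, _ = fitted
        with pytest.raises(ValueError):
            est.predict_proba(np.zeros((3, 64)))

    def test_save_load_roundtrip(self, fitted, tmp_path):
        est, X = fitted
        est.save(tmp_path / "model")
        back = clf.BlastoidClassifier.load(tmp_path / "model")
        np.testing.assert_array_equal(back.predict_proba(X[:8]), est.predict_proba(X[:8]))

    def test_sklearn_params_roundtrip(self):
        est = clf.BlastoidClassifier(epochs=3, learning_rate=1e-3)
        params = est.get_params()
        clone = clf.BlastoidClassifier(**params)
        assert clone.get_params() == params


class TestAblation:
    def test_table_shape_and_determinism(self, balanced_tiles):
        images, _, codes, _ = balanced_tiles
        Xtr, ytr = images[:100], codes[:100]
        Xva, yva = images[500:560], codes[500:560]
        cfg = clf.TrainConfig(epochs=1, input_size=64, seed=0)
        t1 = clf.ablate_augmentations(Xtr, ytr, Xva, yva, cfg)
        t2 = clf.ablate_augmentations(Xtr, ytr, Xva, yva, cfg)
        assert len(t1) == 7
        assert set(t1["ablation"]) == {
            "full", "w/o hflip", "w/o vflip", "w/o jitter", "w/o scaling", "w/o erasing", "none",
        }
        assert t1.equals(t2)
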