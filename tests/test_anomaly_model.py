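"""Adversarial auto-encoder: contracts, losses, training behaviour."""

import numpy as np
import pytest

from minipae.anomaly_model import (
    AnomalyModel,
    ModelConfig,
    anomaly_score,
    build_model,
    compute_losses,
    score_slices,
    train,
)


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(image_size=32, base_channels=4, epochs=2, batch_size=8, seed=3)


@pytest.fixture(scope="module")
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg)


class TestBuild:
    def test_forward_pass_preserves_shape(self, tiny_model):
        x = np.random.default_rng(0).uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        xp, _ = tiny_model.generator.forward(x, train=False)
        assert xp.shape == x.shape
        assert np.abs(xp).max() <= 1.0  # tanh output range

    def test_same_seed_gives_identical_initial_parameters(self, tiny_cfg):
        m1, m2 = build_model(tiny_cfg), build_model(tiny_cfg)
        for p1, p2 in zip(m1.generator.params(), m2.generator.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_discriminator_probability_in_unit_interval(self, tiny_model, rng):
        x = rng.uniform(-1, 1, (3, 1, 32, 32)).astype(np.float32)
        p = tiny_model.discriminator_prob(x)
        assert p.shape == (3,)
        assert ((p > 0) & (p < 1)).all()

    def test_layer_counts_scale_with_image_size(self):
        # 512-pixel models have 8 encoder and 8 discriminator body layers
        assert ModelConfig(image_size=512).n_down == 8
        assert ModelConfig(image_size=64).n_down == 5

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(image_size=4).n_down
        with pytest.raises(ValueError):
            ModelConfig(image_size=48).n_down  # not a power of 2


class TestComputeLosses:
    def test_perfect_reconstruction_zeroes_contextual_and_latent(self):
        x = np.ones((2, 1, 4, 4))
        z = np.ones((2, 8))
        t = compute_losses(x, x, z, z, np.zeros(2), np.zeros(2))
        assert t.contextual == 0.0 and t.latent == 0.0

    def test_hand_computed_l1(self):
        x = np.zeros((1, 1, 2, 2))
        xp = np.ones((1, 1, 2, 2))
        t = compute_losses(x, xp, np.zeros(2), np.zeros(2), np.zeros(1), np.zeros(1))
        assert t.contextual == 1.0

    def test_weight_selection(self):
        x = np.zeros((1, 1, 2, 2))
        xp = np.full((1, 1, 2, 2), 0.5)
        t = compute_losses(x, xp, np.zeros(2), np.ones(2), np.zeros(1), np.zeros(1),
                           weights=(1.0, 0.0, 0.0))
        assert t.total == pytest.approx(t.contextual)

    def test_total_is_weighted_sum(self):
        x = np.zeros((1, 1, 2, 2))
        xp = np.full((1, 1, 2, 2), 0.25)
        t = compute_losses(x, xp, np.zeros(3), np.ones(3), np.zeros(1), np.zeros(1),
                           weights=(2.0, 3.0, 0.5))
        assert t.total == pytest.approx(2 * t.contextual + 3 * t.latent + 0.5 * t.adversarial)

    def test_all_terms_non_negative(self, rng):
        x = rng.uniform(-1, 1, (2, 1, 4, 4))
        xp = rng.uniform(-1, 1, (2, 1, 4, 4))
        t = compute_losses(x, xp, rng.normal(size=4), rng.normal(size=4),
                           rng.normal(size=2), rng.normal(size=2))
        assert t.contextual >= 0 and t.latent >= 0 and t.adversarial >= 0


class TestTrain:
    def test_emphysema_label_in_training_set_rejected(self, tiny_cfg, rng):
        x = rng.uniform(-1, 1, (8, 32, 32))
        m = build_model(tiny_cfg)
        with pytest.raises(ValueError):
            train(m, x, labels=["normal"] * 7 + ["emphysema"], config=tiny_cfg)

    def test_history_length_and_progress(self, tiny_cfg, rng):
        # structured slices (a dark disc on bright background) are learnable
        yy, xx = np.mgrid[0:32, 0:32]
        base = np.where((yy - 16) ** 2 + (xx - 16) ** 2 < 100, -0.6, 0.4)
        x = base + rng.normal(0, 0.05, (24, 32, 32))
        cfg = ModelConfig(image_size=32, base_channels=4, epochs=6, batch_size=8, seed=1)
        m = build_model(cfg)
        train(m, x, config=cfg)
        assert len(m.history["contextual"]) == cfg.epochs
        assert m.history["contextual"][-1] < m.history["contextual"][0]

    def test_fixed_seed_reproducible_history(self, rng):
        x = rng.uniform(-1, 1, (12, 32, 32))
        cfg = ModelConfig(image_size=32, base_channels=4, epochs=2, batch_size=8, seed=5)
        h1 = train(build_model(cfg), x, config=cfg).history
        h2 = train(build_model(cfg), x, config=cfg).history
        assert h1 == h2


class TestScoring:
    @pytest.fixture(scope="class")
    def scored(self, rng=None):
        rng = np.random.default_rng(11)
        cfg = ModelConfig(image_size=32, base_channels=4, epochs=3, batch_size=8, seed=2)
        yy, xx = np.mgrid[0:32, 0:32]
        base = np.where((yy - 16) ** 2 + (xx - 16) ** 2 < 120, -0.4, 0.5)
        x_train = base + rng.normal(0, 0.05, (24, 32, 32))
        m = train(build_model(cfg), x_train, config=cfg)
        x_test = base + rng.normal(0, 0.05, (10, 32, 32))
        results = score_slices(m, x_test)
        return m, x_test, results

    def test_scores_in_unit_interval(self, scored):
        _, _, results = scored
        for r in results:
            assert 0.0 <= r.score <= 1.0

    def test_minmax_normalization_endpoints(self, scored):
        _, _, results = scored
        scores = [r.score for r in results]
        assert min(scores) == 0.0 and max(scores) == 1.0

    def test_single_slice_uses_calibration(self, scored):
        m, x_test, results = scored
        r = anomaly_score(m, x_test[0])
        assert r.score == pytest.approx(results[0].score, abs=1e-6)

    def test_single_slice_without_calibration_sigmoid_fallback(self, scored):
        m, x_test, _ = scored
        cal = m.calibration
        try:
            m.calibration = None
            r = anomaly_score(m, x_test[0])
            assert 0.0 < r.score < 1.0
        finally:
            m.calibration = cal

    def test_planted_blob_scores_higher_than_training_like_slice(self, scored):
        """A localised low-intensity anomaly raises the anomaly score."""
        m, x_test, _ = scored
        clean = x_test[0].copy()
        blob = clean.copy()
        blob[10:18, 10:18] = -1.0  # dark anomaly inside the disc
        r_clean = anomaly_score(m, clean)
        r_blob = anomaly_score(m, blob)
        assert r_blob.raw_score > r_clean.raw_score
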