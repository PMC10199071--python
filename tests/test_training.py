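"""Loss semantics, schedule, augmentations, and training mechanics."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from octlayers.backbone import ArchitectureConfig, DilationBlockSpec, build_model
from octlayers.training import (
    TrainingConfig,
    TrainingSample,
    augment_horizontal_flip,
    augment_vertical_position,
    lr_schedule,
    normalize,
    sse_loss,
    sse_loss_grad,
    train,
)
from tests.conftest import make_training_samples


def sample_with(heights, H=32, W=None, annotation=None):
    heights = np.asarray(heights, dtype=np.float32)
    W = W or heights.shape[1]
    ann = np.ones_like(heights, dtype=bool) if annotation is None else annotation
    rng = np.random.default_rng(0)
    return TrainingSample(image=rng.random((H, W), dtype=np.float32),
                         heights=heights, annotation=ann)


class TestSseLoss:
    def test_zero_for_perfect_prediction(self):
        t = np.random.default_rng(0).random((3, 8))
        m = np.ones_like(t, dtype=bool)
        assert sse_loss(t, t, m) == 0.0

    def test_single_annotated_error(self):
        pred = np.zeros((1, 4))
        target = np.zeros((1, 4))
        pred[0, 2] = 2.0
        mask = np.zeros((1, 4), dtype=bool)
        mask[0, 2] = True
        assert sse_loss(pred, target, mask) == pytest.approx(4.0)

    def test_sum_semantics_masking_halves_loss(self):
        pred = np.ones((2, 10))
        target = np.zeros((2, 10))
        full = np.ones((2, 10), dtype=bool)
        half = full.copy()
        half[:, 5:] = False
        assert sse_loss(pred, target, half) == pytest.approx(
            0.5 * sse_loss(pred, target, full))

    def test_unannotated_entries_never_contribute(self, rng):
        pred = rng.random((3, 16))
        target = rng.random((3, 16))
        mask = rng.random((3, 16)) < 0.5
        noisy_pred = pred.copy()
        noisy_pred[~mask] += 100.0  # corrupt only unannotated entries
        assert sse_loss(noisy_pred, target, mask) == pytest.approx(
            sse_loss(pred, target, mask))
        np.testing.assert_array_equal(sse_loss_grad(noisy_pred, target, mask)[~mask], 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sse_loss(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 3), dtype=bool))


class TestLrSchedule:
    def test_closed_form(self):
        cfg = TrainingConfig()
        assert lr_schedule(0, cfg) == pytest.approx(1e-3)
        assert lr_schedule(1, cfg) == pytest.approx(1e-3 * np.exp(-0.1))
        assert lr_schedule(35, cfg) == pytest.approx(1e-3 * np.exp(-3.5))


class TestHorizontalFlip:
    def test_involution(self):
        s = sample_with(np.arange(12, dtype=float).reshape(3, 4))
        rng = np.random.default_rng(0)
        twice = augment_horizontal_flip(
            augment_horizontal_flip(s, rng, force=True), rng, force=True)
        np.testing.assert_array_equal(twice.image, s.image)
        np.testing.assert_array_equal(twice.heights, s.heights)

    def test_columns_mirrored_consistently(self):
        s = sample_with(np.arange(8, dtype=float).reshape(2, 4))
        f = augment_horizontal_flip(s, np.random.default_rng(0), force=True)
        w = s.image.shape[1]
        for x in range(w):
            np.testing.assert_array_equal(f.heights[:, x], s.heights[:, w - 1 - x])
            np.testing.assert_array_equal(f.image[:, x], s.image[:, w - 1 - x])

    def test_probability_zero_is_identity(self):
        s = sample_with(np.ones((3, 4)))
        out = augment_horizontal_flip(s, np.random.default_rng(0), prob=0.0)
        assert out is s


class TestVerticalPosition:
    def cfg(self, offset=6.0, vshift=8):
        return TrainingConfig(center_offset_above_bm=offset, vshift_range=vshift)

    def test_centered_input_with_zero_shift_is_identity(self):
        H = 32
        cfg = self.cfg()
        bm_height = H / 2 + cfg.center_offset_above_bm  # reference lands mid-image
        s = sample_with(np.array([[bm_height] * 4]), H=H)
        out = augment_vertical_position(s, np.random.default_rng(0), cfg, shift=0)
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.heights, s.heights)

    def test_rigid_translation_of_heights(self):
        H, cfg = 32, self.cfg()
        bm_height = H / 2 + cfg.center_offset_above_bm
        s = sample_with(np.array([[bm_height] * 4]), H=H)
        out = augment_vertical_position(s, np.random.default_rng(0), cfg, shift=10)
        np.testing.assert_allclose(out.heights, s.heights + 10)

    def test_heights_outside_image_lose_annotation(self):
        H, cfg = 32, self.cfg()
        s = sample_with(np.array([[3.0] * 3,
                                  [H / 2 + cfg.center_offset_above_bm] * 3]), H=H)
        out = augment_vertical_position(s, np.random.default_rng(0), cfg, shift=-10)
        assert not out.annotation[0].any()  # top layer pushed above row 0
        assert out.annotation[1].all()

    def test_requires_bm_annotation(self):
        s = sample_with(np.array([[10.0] * 4]),
                        annotation=np.zeros((1, 4), dtype=bool))
        with pytest.raises(ValueError, match="BM"):
            augment_vertical_position(s, np.random.default_rng(0), self.cfg())

    def test_shift_distribution_uniform(self):
        """Empirical KS check of the uniform integer shift over 10^4 draws."""
        H, v = 64, 18
        cfg = TrainingConfig(center_offset_above_bm=6.0, vshift_range=v)
        bm_height = H / 2 + cfg.center_offset_above_bm
        s = sample_with(np.array([[bm_height] * 2]), H=H)
        gen = np.random.default_rng(123)
        draws = np.array([
            augment_vertical_position(s, gen, cfg).heights[0, 0] - bm_height
            for _ in range(10_000)
        ])
        assert draws.min() >= -v and draws.max() <= v
        # KS against the continuous uniform; discreteness adds at most ~1/(2v) bias
        d, _ = stats.kstest(draws, stats.uniform(loc=-v, scale=2 * v).cdf)
        assert d < 0.05


class TestNormalize:
    def test_zero_mean_unit_variance(self, rng):
        img = rng.random((16, 16)).astype(np.float32)
        out = normalize(img)
        assert abs(out.mean()) < 1e-6 and abs(out.var() - 1) < 1e-5

    def test_affine_invariance(self, rng):
        img = rng.random((8, 8)).astype(np.float32)
        np.testing.assert_allclose(normalize(3.0 * img + 7.0), normalize(img),
                                   atol=1e-5)

    def test_constant_image_fallback(self):
        np.testing.assert_array_equal(normalize(np.full((4, 4), 3.0)), 0.0)


class TestTrainLoop:
    def tiny_model(self, seed=0):
        cfg = ArchitectureConfig(
            init_channels=(2, 3, 4), feature_width=4, attention_channels=4,
            dilation_blocks=(DilationBlockSpec(3, 1, 2),), n_output_layers=3)
        return build_model(cfg, seed=seed)

    def tcfg(self, **kw):
        defaults = dict(epochs=2, center_offset_above_bm=8.0, vshift_range=3, seed=5)
        defaults.update(kw)
        return TrainingConfig(**defaults)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(self.tiny_model(), [], self.tcfg())

    def test_history_lr_matches_schedule(self, small_sim_config):
        from dataclasses import replace as drep
        cfg = drep(small_sim_config, height=40, width=32, base_bm_row=26.0,
                   bm_curve_amplitude=2.0, bm_tilt=1.0, rpe_offset=6.0,
                   ez_offset=5.0, vertical_jitter=2.0, druse_amplitude=(2.0, 4.0))
        data = make_training_samples(cfg, 4, seed=0)
        tcfg = self.tcfg(epochs=3)
        result = train(self.tiny_model(), data, tcfg)
        expected = [lr_schedule(e, tcfg) for e in range(3)]
        np.testing.assert_allclose(result.history["lr"], expected)

    def test_same_seed_identical_history(self, small_sim_config):
        from dataclasses import replace as drep
        cfg = drep(small_sim_config, height=40, width=32, base_bm_row=26.0,
                   bm_curve_amplitude=2.0, bm_tilt=1.0, rpe_offset=6.0,
                   ez_offset=5.0, vertical_jitter=2.0, druse_amplitude=(2.0, 4.0))
        data = make_training_samples(cfg, 6, seed=1)
        val = make_training_samples(cfg, 2, seed=2)
        h1 = train(self.tiny_model(seed=4), data, self.tcfg(), val_dataset=val).history
        h2 = train(self.tiny_model(seed=4), data, self.tcfg(), val_dataset=val).history
        assert h1 == h2

    def test_loss_decreases_on_easy_problem(self, small_sim_config):
        from dataclasses import replace as drep
        cfg = drep(small_sim_config, height=40, width=32, base_bm_row=26.0,
                   bm_curve_amplitude=2.0, bm_tilt=1.0, rpe_offset=6.0,
                   ez_offset=5.0, vertical_jitter=2.0, druse_amplitude=(2.0, 4.0),
                   drusen_per_bscan=0.5)
        data = make_training_samples(cfg, 12, seed=3)
        result = train(self.tiny_model(seed=1), data, self.tcfg(epochs=6))
        sse = result.history["train_sse"]
        assert sse[-1] < sse[0]
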