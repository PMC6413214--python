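import numpy as np
import pytest

from pigparts.core import FrameAnnotation
from pigparts.encoder import TargetMaps, encode_frame
from pigparts.network import (BlockKind, DEFAULT_WIDTHS, HourglassModel,
                              LayerBlockSpec, TrainConfig, TrainingDivergenceError,
                              _selective_loss_grad, build_model, effective_strides,
                              hourglass_spec, predict_maps, receptive_field,
                              selective_loss, train)
from pigparts.scenes import SceneConfig, generate_dataset

TINY_WIDTHS = (4, 6, 8, 8, 8)


def tiny_scene(seed=0):
    cfg = SceneConfig(image_size=(64, 96), n_pigs_range=(1, 2),
                      body_length_range=(18.0, 30.0), abutting_fraction=0.0,
                      noise_sigma=0.02, seed=seed)
    return generate_dataset(1, cfg, seed=seed)[0]


class TestArchitectureAnalytics:
    def test_spec_shape(self):
        spec = hourglass_spec()
        assert len(spec) == 41
        kinds = [b.kind for b in spec]
        assert kinds.count(BlockKind.MAX_POOL) == 5
        assert kinds.count(BlockKind.MAX_UNPOOL) == 5
        assert kinds[0] is BlockKind.INPUT and kinds[-1] is BlockKind.OUTPUT
        assert spec[-1].channels_out == 16

    def test_effective_strides(self):
        spec = hourglass_spec()
        es = effective_strides(spec)
        assert max(es) == 32.0          # bottleneck
        assert es[-1] == 1.0            # output back at input resolution
        # the bottleneck pool/unpool produce the printed 16, 32, 16 pattern
        peak = es.index(32.0)
        assert es[peak - 1] == 16.0 and es[peak + 1] == 16.0

    def test_no_pooling_keeps_stride_one(self):
        spec = [LayerBlockSpec(BlockKind.INPUT),
                LayerBlockSpec(BlockKind.CONV_BLOCK, kernel_width=3),
                LayerBlockSpec(BlockKind.CONV_BLOCK, kernel_width=3)]
        assert effective_strides(spec) == [1.0, 1.0, 1.0]
        assert receptive_field(spec) == [1, 3, 5]

    def test_receptive_field_profile(self):
        rf = receptive_field(hourglass_spec())
        assert rf[:5] == [1, 3, 5, 5, 9]
        assert rf[-1] == 363
        assert (rf[-1] - 1) // 2 == 181
        es = effective_strides(hourglass_spec())
        # rf holds at 181 across the bottleneck (conv, pool, unpool)
        bottleneck = es.index(32.0)
        assert rf[bottleneck - 1] == rf[bottleneck] == rf[bottleneck + 1] == 181
        assert 213 in rf  # first decoder conv widens 181 -> 213


class TestModel:
    def test_output_shape_matches_input(self):
        model = build_model(widths=TINY_WIDTHS, seed=0)
        y = model.forward(np.zeros((64, 96, 3), dtype=np.float32), train=False)
        assert y.shape == (64, 96, 16)

    def test_default_width_parameter_budget(self):
        model = build_model(widths=DEFAULT_WIDTHS, seed=0)
        assert 3.5e6 <= model.parameter_count() <= 4.5e6

    def test_forward_deterministic_for_fixed_seed(self):
        x = np.random.default_rng(1).normal(size=(32, 32, 3)).astype(np.float32)
        y1 = build_model(widths=TINY_WIDTHS, seed=5).forward(x, train=False)
        y2 = build_model(widths=TINY_WIDTHS, seed=5).forward(x, train=False)
        np.testing.assert_array_equal(y1, y2)

    def test_non_multiple_of_32_rejected_by_forward_but_padded_by_predict(self):
        model = build_model(widths=TINY_WIDTHS, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((50, 96, 3), dtype=np.float32))
        maps = predict_maps(model, np.zeros((50, 70, 3)))
        assert maps.shape == (16, 50, 70)


class TestSelectiveLoss:
    def _target(self, rng):
        t = TargetMaps.zeros(32, 32)
        t.part_maps[:] = rng.uniform(size=t.part_maps.shape)
        t.assoc_mask[:] = rng.uniform(size=t.assoc_mask.shape) < 0.3
        t.assoc_maps[:] = rng.normal(size=t.assoc_maps.shape) * t.assoc_mask
        return t

    def test_zero_when_equal(self):
        t = self._target(np.random.default_rng(0))
        assert selective_loss(t.stacked(), t) == 0.0

    def test_masked_out_pixels_do_not_contribute(self):
        rng = np.random.default_rng(1)
        t = self._target(rng)
        pred = t.stacked().copy()
        perturbed = pred.copy()
        perturbed[4:] += rng.normal(size=perturbed[4:].shape) * (1 - t.assoc_mask)
        assert selective_loss(perturbed, t) == selective_loss(pred, t) == 0.0

    def test_constant_shift_on_part_channels(self):
        t = self._target(np.random.default_rng(2))
        pred = t.stacked().copy()
        pred[:4] += 0.25
        assert selective_loss(pred, t) == pytest.approx(0.25 ** 2)

    def test_gradient_zero_at_masked_pixels(self):
        rng = np.random.default_rng(3)
        t = self._target(rng)
        pred = t.stacked().transpose(1, 2, 0) + rng.normal(size=(32, 32, 16))
        _, grad = _selective_loss_grad(pred.astype(np.float32), t)
        mask = t.assoc_mask.transpose(1, 2, 0)
        np.testing.assert_array_equal(grad[..., 4:] * (1 - mask), 0.0)

    def test_shape_mismatch_rejected(self):
        t = self._target(np.random.default_rng(4))
        with pytest.raises(ValueError):
            selective_loss(np.zeros((16, 16, 16)), t)


class TestTraining:
    def test_single_frame_loss_collapses(self):
        image, frame = tiny_scene(seed=2)
        model = build_model(widths=TINY_WIDTHS, seed=0)
        cfg = TrainConfig(epochs=80, learning_rate=1e-2, augment=None, seed=0)
        _, history = train(model, [(image, frame)], cfg)
        assert history[-1] < 0.3 * history[0]
        # steady downward trend, no oscillating divergence
        assert np.mean(history[-10:]) < np.mean(history[:10])

    def test_identical_seeds_identical_histories(self):
        image, frame = tiny_scene(seed=4)
        histories = []
        for _ in range(2):
            model = build_model(widths=TINY_WIDTHS, seed=1)
            _, h = train(model, [(image, frame)],
                         TrainConfig(epochs=4, seed=9))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_nan_input_aborts_with_diagnostic(self):
        image, frame = tiny_scene(seed=5)
        bad = np.full_like(image, np.nan)
        model = build_model(widths=TINY_WIDTHS, seed=0)
        with pytest.raises(TrainingDivergenceError):
            train(model, [(bad, frame)], TrainConfig(epochs=1, augment=None))

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(widths=TINY_WIDTHS), [], TrainConfig())
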