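"""Translator: network contracts, gradient correctness of the autodiff
engine, training behaviour, prediction and tile stitching."""

import numpy as np
import pytest

from virtustain import metrics, translator
from virtustain.errors import FormatError, ShapeError, ValidationError
from virtustain.nn import Parameter


def small_config(**kw):
    defaults = dict(depth=3, base_channels=4, iterations=10, batch_size=2,
                    seed=0, input_size=64)
    defaults.update(kw)
    return translator.TranslatorConfig(**defaults)


class TestAutodiff:
    """Numerical gradient checks of the engine the networks train on."""

    @staticmethod
    def _num_grad(fval, arr, eps=1e-6):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            old = arr[idx]
            arr[idx] = old + eps
            fp = fval()
            arr[idx] = old - eps
            fm = fval()
            arr[idx] = old
            g[idx] = (fp - fm) / (2 * eps)
        return g

    @pytest.mark.parametrize("stride,k,pad", [(1, 3, 1), (2, 4, 1)])
    def test_conv2d_gradients(self, rng, stride, k, pad):
        x = rng.normal(size=(2, 3, 8, 8))
        w = rng.normal(size=(4, 3, k, k))
        b = rng.normal(size=4)
        px, pw, pb = Parameter(x), Parameter(w), Parameter(b)

        def loss():
            return px.conv2d(pw, pb, stride=stride, pad=pad).mean_sq()

        out = loss()
        out.backward()
        for p in (px, pw, pb):
            ng = self._num_grad(lambda: float(loss().data), p.data)
            assert np.abs(ng - p.grad).max() < 1e-6 * max(np.abs(ng).max(), 1.0)

    def test_composite_graph_gradients(self, rng):
        x = rng.normal(size=(1, 2, 8, 8))
        w = rng.normal(size=(2, 2, 4, 4))
        b = rng.normal(size=2)
        y = rng.normal(size=(1, 2, 8, 8))
        px, pw, pb, py = Parameter(x), Parameter(w), Parameter(b), Parameter(y)

        def loss():
            h = px.conv2d(pw, pb, stride=2, pad=1).leaky_relu().upsample2()
            return (h.concat(py.tanh()) - 0.3).mean_abs()

        loss().backward()
        for p in (px, pw, pb, py):
            ng = self._num_grad(lambda: float(loss().data), p.data)
            assert np.abs(ng - p.grad).max() < 1e-5


class TestGenerator:
    def test_output_shape_matches_input(self):
        gen = translator.build_generator(small_config())
        out = gen(np.zeros((1, 1, 64, 64), dtype=np.float32))
        assert out.shape == (1, 1, 64, 64)

    def test_zero_parameters_give_constant_output(self, rng):
        gen = translator.build_generator(small_config())
        for p in gen.parameters():
            p.data[...] = 0.0
        out = gen(rng.normal(size=(1, 1, 64, 64)).astype(np.float32))
        assert np.allclose(out, out.flat[0])

    def test_parameter_count_matches_layer_arithmetic(self):
        """Layer-by-layer sum over the declared architecture."""
        c, d = 16, 3
        gen = translator.build_generator(small_config(base_channels=c, depth=d))
        expected = c * 1 * 9 + c  # entry 3x3
        for i in range(d):  # encoder 4x4 stride 2
            expected += (c * 2 ** (i + 1)) * (c * 2**i) * 16 + c * 2 ** (i + 1)
        for i in range(d, 0, -1):  # decoder: up-conv + merge conv, both 3x3
            ci, co = c * 2**i, c * 2 ** (i - 1)
            expected += co * ci * 9 + co
            expected += co * (2 * co) * 9 + co
        expected += 1 * c * 9 + 1  # exit 3x3
        assert gen.num_parameters() == expected

    def test_invalid_input_size_rejected(self):
        with pytest.raises(ValidationError):
            small_config(input_size=60)  # not divisible by 2^3


class TestDiscriminator:
    def test_finite_score_grid_and_extent(self, rng):
        disc = translator.build_discriminator(small_config())
        xy = rng.normal(size=(1, 2, 64, 64)).astype(np.float32)
        score = disc(xy)
        # two stride-2 4x4 convs: 64 -> 32 -> 16; final 3x3 keeps 16
        assert score.shape == (1, 1, 16, 16)
        assert np.all(np.isfinite(score))

    def test_channel_concatenation_is_asymmetric(self, rng):
        disc = translator.build_discriminator(small_config())
        a = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        b = rng.normal(size=(1, 1, 64, 64)).astype(np.float32)
        s_ab = disc(np.concatenate([a, b], axis=1))
        s_ba = disc(np.concatenate([b, a], axis=1))
        assert not np.allclose(s_ab, s_ba)

    def test_channel_mismatch_rejected(self, rng):
        disc = translator.build_discriminator(small_config())
        with pytest.raises(ShapeError):
            disc(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))


class TestTraining:
    def test_single_pair_overfit(self, training_pairs):
        """Pixel-loss-only training overfits one pair: training MAE drops
        below 10% of the pair's intensity range."""
        pair = training_pairs[0]
        cfg = small_config(
            base_channels=8, iterations=400, batch_size=1,
            adversarial_loss_weight=0.0,
        )
        model, log = translator.train([pair], cfg)
        pred = model.predict(pair.phase)
        target = translator.normalize_image(pair.fluorescence)
        assert metrics.absolute_error(target, pred) < 0.1 * np.ptp(target)

    def test_training_deterministic_for_seed(self, training_pairs):
        cfg = small_config(iterations=12)
        _, log1 = translator.train(training_pairs[:4], cfg)
        _, log2 = translator.train(training_pairs[:4], cfg)
        assert log1.generator_loss == log2.generator_loss
        assert log1.discriminator_loss == log2.discriminator_loss

    def test_unet_only_baseline_skips_discriminator(self, training_pairs):
        """adversarial_loss_weight=0 is pure supervised U-Net regression;
        the generator loss curve is unchanged by the discriminator's
        (non-)existence and no discriminator loss is recorded."""
        cfg = small_config(iterations=8, adversarial_loss_weight=0.0)
        _, log = translator.train(training_pairs[:4], cfg)
        assert all(np.isnan(v) for v in log.discriminator_loss)
        cfg2 = small_config(iterations=8, adversarial_loss_weight=0.0,
                            pixel_loss_weight=100.0)
        _, log2 = translator.train(training_pairs[:4], cfg2)
        assert log.generator_loss == log2.generator_loss

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            translator.train([], small_config())


@pytest.fixture(scope="module")
def tiny_model(training_pairs):
    cfg = small_config(base_channels=4, iterations=30)
    model, _ = translator.train(training_pairs[:6], cfg)
    return model


class TestPredict:
    def test_deterministic(self, tiny_model, training_pairs):
        p = training_pairs[0].phase
        np.testing.assert_array_equal(
            tiny_model.predict(p), tiny_model.predict(p)
        )

    def test_output_range(self, tiny_model, training_pairs):
        out = tiny_model.predict(training_pairs[0].phase)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_non_divisible_input_padded_and_cropped(self, tiny_model, rng):
        out = tiny_model.predict(rng.random((70, 92)))
        assert out.shape == (70, 92)

    def test_non_2d_input_rejected(self, tiny_model, rng):
        with pytest.raises(ShapeError):
            tiny_model.predict(rng.random((2, 64, 64)))

    def test_metric_pipeline_on_heldout_pair(self, tiny_model, heldout_pairs):
        """Both r_s against the noisy target and against the noise-free
        truth are computable on a prediction (denoising means the latter
        may exceed the former; neither is an error)."""
        pair = heldout_pairs[0]
        pred = tiny_model.predict(pair.phase)
        r_noisy = metrics.pearson_source(
            translator.normalize_image(pair.fluorescence), pred
        )
        r_truth = metrics.pearson_source(
            translator.normalize_image(pair.ground_truth), pred
        )
        assert np.isfinite(r_noisy) and np.isfinite(r_truth)


class TestPredictTiles:
    def test_single_tile_equals_predict(self, tiny_model, training_pairs):
        p = training_pairs[0].phase
        np.testing.assert_allclose(
            translator.predict_tiles(tiny_model, [[p]], overlap=0),
            tiny_model.predict(p),
        )

    def test_mosaic_dimensions(self, tiny_model, rng):
        tiles = [[rng.random((64, 64)) for _ in range(3)] for _ in range(2)]
        mosaic = translator.predict_tiles(tiny_model, tiles, overlap=8)
        assert mosaic.shape == (2 * 64 - 8, 3 * 64 - 2 * 8)  # 120 x 176

    def test_blending_preserves_constants(self, tiny_model):
        tiles = [[np.full((64, 64), 0.7) for _ in range(2)] for _ in range(2)]
        mosaic = translator.predict_tiles(tiny_model, tiles, overlap=8)
        # constant input -> identical per-tile prediction fields; feathered
        # overlaps of equal values must reproduce those values exactly
        single = tiny_model.predict(tiles[0][0])
        assert np.allclose(mosaic[:56, :56], single[:56, :56], atol=1e-6)
        interior = mosaic[56:64, 56:64]
        assert np.ptp(mosaic) == pytest.approx(np.ptp(single), abs=1e-6)

    def test_inconsistent_tiles_rejected(self, tiny_model, rng):
        with pytest.raises(ShapeError):
            translator.predict_tiles(
                tiny_model, [[rng.random((64, 64)), rng.random((32, 32))]]
            )


class TestPersistence:
    def test_roundtrip(self, training_pairs, tmp_path):
        cfg = small_config(iterations=5)
        model, _ = translator.train(training_pairs[:2], cfg)
        path = tmp_path / "model.npz"
        translator.save_model(model, path)
        loaded = translator.load_model(path)
        p = training_pairs[0].phase
        np.testing.assert_array_equal(model.predict(p), loaded.predict(p))

    def test_version_mismatch_refused(self, training_pairs, tmp_path):
        import json

        cfg = small_config(iterations=2)
        model, _ = translator.train(training_pairs[:2], cfg)
        path = tmp_path / "model.npz"
        translator.save_model(model, path)
        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            arrays = {k: z[k] for k in z.files if k != "meta"}
        meta["version"] = "other-format-9"
        np.savez(path, meta=json.dumps(meta), **arrays)
        with pytest.raises(FormatError):
            translator.load_model(path)
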