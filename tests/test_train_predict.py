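import numpy as np
import pytest
from scipy.signal import convolve2d

from scopesr import (
    Crappifier,
    ImageStack,
    IntensityRange,
    ModelSpec,
    SlideConfig,
    TiledDataset,
    TrainConfig,
    benchmark,
    bilinear_upscale,
    build_resunet,
    mixed_loss,
    ms_ssim,
    predict_image,
    psnr,
    ssim,
    train_model,
)
from scopesr.train_predict import _MSSSIM_WEIGHTS_5


# --- independent MS-SSIM oracle: literal multi-scale definition ------------
def _oracle_gaussian_kernel(win=11, sigma=1.5):
    x = np.arange(win) - (win - 1) / 2
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def _oracle_msssim(a, b, levels=3, data_range=1.0):
    """Straight-line MS-SSIM from its definition, via scipy valid convolution."""
    k1d = _oracle_gaussian_kernel()
    window = np.outer(k1d, k1d)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    weights = np.array(_MSSSIM_WEIGHTS_5[:levels])
    weights = weights / weights.sum()

    def filt(img):
        return convolve2d(img, window, mode="valid")

    a = a.astype(np.float64).copy()
    b = b.astype(np.float64).copy()
    result = 1.0
    for level in range(levels):
        mu_a, mu_b = filt(a), filt(b)
        va = filt(a * a) - mu_a**2
        vb = filt(b * b) - mu_b**2
        vab = filt(a * b) - mu_a * mu_b
        cs = ((2 * vab + c2) / (va + vb + c2)).mean()
        if level < levels - 1:
            result *= max(cs, 0.0) ** weights[level]
            h, w = a.shape
            a = a[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
            b = b[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
        else:
            lum = ((2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1) * ((2 * vab + c2) / (va + vb + c2))).mean()
            result *= max(lum, 0.0) ** weights[level]
    return result


class TestMetrics:
    def test_psnr_closed_forms(self):
        a = np.full((32, 32), 0.5, np.float32)
        assert psnr(a, a) == 100.0
        assert psnr(a, a + np.float32(0.1)) == pytest.approx(20.0, abs=1e-4)
        with pytest.raises(ValueError, match="data_range"):
            psnr(a, a, data_range=0.0)

    def test_psnr_matches_reference(self, rng):
        from skimage.metrics import peak_signal_noise_ratio

        for _ in range(10):
            a = rng.random((64, 64)).astype(np.float32)
            b = rng.random((64, 64)).astype(np.float32)
            assert psnr(a, b) == pytest.approx(
                peak_signal_noise_ratio(a, b, data_range=1.0), abs=1e-6
            )

    def test_ssim_matches_reference(self, rng):
        from skimage.metrics import structural_similarity

        for _ in range(10):
            a = rng.random((64, 64)).astype(np.float32)
            b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1).astype(np.float32)
            ref = structural_similarity(
                a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False,
            )
            assert ssim(a, b) == pytest.approx(ref, abs=1e-4)

    def test_msssim_matches_oracle(self, rng):
        for _ in range(10):
            a = rng.random((96, 96)).astype(np.float32)
            b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1).astype(np.float32)
            assert ms_ssim(a, b, levels=3) == pytest.approx(
                _oracle_msssim(a, b, levels=3), abs=1e-4
            )

    def test_msssim_identity_and_symmetry(self, rng):
        a = rng.random((64, 64)).astype(np.float32)
        b = rng.random((64, 64)).astype(np.float32)
        assert ms_ssim(a, a) == pytest.approx(1.0, abs=1e-6)
        assert ms_ssim(a, b) == pytest.approx(ms_ssim(b, a), abs=1e-7)
        assert 0.0 <= ms_ssim(a, b) <= 1.0

    def test_msssim_too_small_advises_fewer_levels(self, rng):
        a = rng.random((16, 16)).astype(np.float32)
        with pytest.raises(ValueError, match="fewer levels"):
            ms_ssim(a, a, levels=3)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.84, 1.0])
    def test_mixed_loss_zero_on_identical(self, rng, alpha):
        a = rng.random((64, 64)).astype(np.float32)
        assert mixed_loss(a, a, alpha) == pytest.approx(0.0, abs=1e-7)

    def test_mixed_loss_l1_limit(self):
        a = np.full((64, 64), 0.3, np.float32)
        assert mixed_loss(a, a + np.float32(0.2), alpha=0.0) == pytest.approx(0.2, abs=1e-6)

    def test_mixed_loss_recomposition(self, rng):
        a = rng.random((64, 64)).astype(np.float32)
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1).astype(np.float32)
        alpha = 0.84
        expected = alpha * (1 - ms_ssim(a, b)) + (1 - alpha) * np.mean(np.abs(a - b))
        assert mixed_loss(a, b, alpha) == pytest.approx(expected, abs=1e-6)

    def test_mixed_loss_alpha_validation(self, rng):
        a = rng.random((64, 64)).astype(np.float32)
        with pytest.raises(ValueError, match="alpha"):
            mixed_loss(a, a, alpha=1.5)


def _tiny_train_setup(rng, n_tiles=8):
    from scopesr import SpecimenSpec, generate_specimen

    hr = {f"im{i}": generate_specimen(SpecimenSpec(shape=(64, 64), n_spots=6, n_filaments=1, seed=i))
          for i in range(max(1, n_tiles // 4))}
    ds = TiledDataset(
        hr, SlideConfig(32, 0), "train_crappified",
        scale=2, crappifier=Crappifier("poisson", intensity=1.0, gain=200),
        intensity_range=IntensityRange(0.5, 1.5),
    )
    model = build_resunet(ModelSpec(scale=2, base_channels=4, depth=2), seed=0)
    return model, ds


class TestTraining:
    def test_loss_decreases(self, rng):
        model, ds = _tiny_train_setup(rng)
        cfg = TrainConfig(epochs=6, batch_size=4, learning_rate=2e-3, seed=0)
        _, history = train_model(model, ds, None, cfg)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_zero_learning_rate_freezes_params(self, rng):
        model, ds = _tiny_train_setup(rng)
        before = [p.data.copy() for p in model.parameters()]
        cfg = TrainConfig(epochs=1, batch_size=4, learning_rate=0.0, seed=0)
        train_model(model, ds, None, cfg)
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_seeded_runs_identical(self, rng):
        cfg = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=4)
        histories = []
        for _ in range(2):
            model, ds = _tiny_train_setup(rng)
            _, h = train_model(model, ds, ds, cfg)
            histories.append(h)
        assert histories[0] == histories[1]

    def test_empty_dataset_rejected(self, rng):
        model, ds = _tiny_train_setup(rng)
        empty = ds.subset([])
        with pytest.raises(ValueError, match="empty"):
            train_model(model, empty, None, TrainConfig(epochs=1))


class _PointwiseModel:
    """Linear per-pixel stub: y = 0.5 x + 0.1, optional replication upscale."""

    def __init__(self, scale=1):
        self.spec = ModelSpec(scale=scale, base_channels=4, depth=1)

    def predict(self, frames):
        out = 0.5 * frames + 0.1
        if self.spec.scale > 1:
            out = np.repeat(np.repeat(out, self.spec.scale, 2), self.spec.scale, 3)
        return out


class TestPredictImage:
    def test_identity_model_roundtrip(self, rng):
        class Identity(_PointwiseModel):
            def predict(self, frames):
                return frames

        lr = ImageStack(rng.random((100, 100)).astype(np.float32), "YX")
        out = predict_image(Identity(), lr, SlideConfig(32, 8))
        np.testing.assert_allclose(out.data, lr.data, atol=1e-6)

    def test_scale_two_shape(self, rng):
        lr = ImageStack(rng.random((100, 100)).astype(np.float32), "YX")
        out = predict_image(_PointwiseModel(scale=2), lr, SlideConfig(32, 8))
        assert out.spatial_shape == (200, 200)

    def test_tiled_equals_untiled_for_local_model(self, rng):
        lr = ImageStack(rng.random((96, 96)).astype(np.float32), "YX")
        model = _PointwiseModel(scale=2)
        tiled = predict_image(model, lr, SlideConfig(32, 8))
        untiled = np.clip(model.predict(lr.data[None, None])[0, 0], 0, 1)
        np.testing.assert_allclose(tiled.data, untiled, atol=1e-5)


class TestBenchmark:
    def _paired(self, rng, n=3):
        hr = {f"p{i}": ImageStack(rng.random((64, 64)).astype(np.float32), "YX") for i in range(n)}
        lr = {k: bilinear_upscale(v, 1).with_data(v.data[::2, ::2]) for k, v in hr.items()}
        return TiledDataset(hr, None, "benchmark_paired", lr_sources=lr)

    def test_perfect_model_scores_cap(self, rng):
        ds = self._paired(rng)

        class Perfect:
            spec = ModelSpec(scale=2, base_channels=4, depth=1)

            def __init__(self, ds):
                self.ds = ds
                self.i = 0

            def predict(self, frames):
                _, hr = self.ds.get_item(self.i)
                self.i += 1
                return hr.data[None, None]

        result = benchmark(Perfect(ds), ds, tile_config=SlideConfig(32, 0))
        for r in result.records:
            assert r.psnr_model == 100.0
            assert r.ssim_model == pytest.approx(1.0, abs=1e-7)
            assert r.msssim_model == pytest.approx(1.0, abs=1e-6)

    def test_control_is_model_independent(self, rng):
        ds = self._paired(rng)
        res_a = benchmark(_PointwiseModel(scale=2), ds)
        res_b = benchmark(build_resunet(ModelSpec(scale=2, base_channels=4, depth=2), seed=0), ds)
        for ra, rb in zip(res_a.records, res_b.records):
            assert ra.psnr_control == rb.psnr_control
            assert ra.ssim_control == rb.ssim_control

    def test_requires_paired_mode(self, rng):
        hr = {"a": ImageStack(rng.random((64, 64)).astype(np.float32), "YX")}
        ds = TiledDataset(hr, SlideConfig(32, 0), "predict_lr_only")
        with pytest.raises(ValueError, match="benchmark_paired"):
            benchmark(_PointwiseModel(), ds)

    def test_csv_report(self, rng, tmp_path):
        ds = self._paired(rng, n=2)
        result = benchmark(_PointwiseModel(scale=2), ds)
        path = result.to_csv(tmp_path / "bench.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("image_id,psnr_model")
        assert len(lines) == 4  # header + 2 records + mean row
        assert lines[-1].startswith("mean,")
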