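"""CNN building blocks: standardization, rendering, augmentation,
architecture arithmetic and the training contract."""

import numpy as np
import pytest

from eemkit.cnn import (
    CNN1DSpec,
    CNN2DSpec,
    ContourImage,
    ImageAugmentParams,
    TrainConfig,
    augment_matrices_for_images,
    build_1d_cnn,
    build_2d_cnn,
    images_to_array,
    predict_cnn,
    render_contour,
    spectra_to_cnn_input,
    train_model,
    zscore_fit_apply,
)
from eemkit.nn import Dense, Sequential
from eemkit.preprocess import NormalizedEEM, normalize_global
from eemkit.synthetic import EEMGrid


@pytest.fixture(scope="module")
def norm_eem(grid):
    rng = np.random.default_rng(0)
    vals = rng.random(grid.shape) * 255.0
    return NormalizedEEM(grid=grid, values=vals, sample_id="s0", adulteration_pct=10.0)


class TestZScore:
    def test_two_spectra_standardize_to_plus_minus_one(self):
        train = np.stack([np.zeros(6), np.full(6, 2.0)])
        out, _, mean, sd = zscore_fit_apply(train)
        np.testing.assert_allclose(out[0], -1.0)
        np.testing.assert_allclose(out[1], 1.0)
        np.testing.assert_allclose(mean, 1.0)
        np.testing.assert_allclose(sd, 1.0)

    def test_constant_column_maps_to_zero(self):
        train = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        out, _, _, _ = zscore_fit_apply(train)
        np.testing.assert_allclose(out[:, 1], 0.0)

    def test_training_mean_maps_to_zero_vector(self):
        rng = np.random.default_rng(1)
        train = rng.random((10, 4))
        _, (z,), _, _ = zscore_fit_apply(train, train.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_single_training_sample_rejected(self):
        with pytest.raises(ValueError, match="two training"):
            zscore_fit_apply(np.ones((1, 5)))


class TestRenderContour:
    def test_output_shape_and_range(self, norm_eem):
        img = render_contour(norm_eem)
        assert img.pixels.shape == (224, 224, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_deterministic(self, norm_eem):
        a = render_contour(norm_eem)
        b = render_contour(norm_eem)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_normalization_render_commutation(self, grid):
        """Two raw datasets differing by a global scale render to identical
        images once each is normalized by its own global maximum."""
        from eemkit.synthetic import EEMDataset, EEMSample

        rng = np.random.default_rng(2)
        m = rng.random(grid.shape) * 800.0
        ds1 = EEMDataset([EEMSample(grid=grid, intensity=m, adulteration_pct=0)])
        ds2 = EEMDataset([EEMSample(grid=grid, intensity=3.0 * m, adulteration_pct=0)])
        img1 = render_contour(normalize_global(ds1)[0])
        img2 = render_contour(normalize_global(ds2)[0])
        np.testing.assert_array_equal(img1.pixels, img2.pixels)

    def test_non_finite_rejected(self, grid):
        vals = np.full(grid.shape, np.nan)
        with pytest.raises(ValueError, match="finite"):
            render_contour(NormalizedEEM(grid=grid, values=vals))


class TestImageAugmentation:
    def test_63_originals_9_copies_gives_630(self, grid):
        rng = np.random.default_rng(3)
        mats = [NormalizedEEM(grid=grid, values=rng.random(grid.shape) * 255)
                for _ in range(63)]
        out = augment_matrices_for_images(mats, ImageAugmentParams(copies=9, seed=0))
        assert len(out) == 630

    def test_zero_copies_is_identity(self, norm_eem):
        out = augment_matrices_for_images([norm_eem], ImageAugmentParams(copies=0))
        assert out == [norm_eem]

    def test_null_augmentation_exact_copies(self, norm_eem):
        params = ImageAugmentParams(amplitude_range=(1.0, 1.0),
                                    noise_sigma_range=(0.0, 0.0), copies=2, seed=0)
        out = augment_matrices_for_images([norm_eem], params)
        for copy in out[1:]:
            np.testing.assert_allclose(copy.values, norm_eem.values)
            assert copy.augmented

    def test_copies_clipped_at_zero(self, grid):
        mats = [NormalizedEEM(grid=grid, values=np.zeros(grid.shape))]
        out = augment_matrices_for_images(
            mats, ImageAugmentParams(noise_sigma_range=(5.0, 5.0), copies=3, seed=1)
        )
        for copy in out[1:]:
            assert copy.values.min() >= 0.0


class TestArchitectures:
    def test_1d_parameter_arithmetic(self):
        """Valid-padding arithmetic: 65 -> conv 63 -> pool 31 -> flatten
        496; conv holds 3*1*16+16 = 64 parameters, dense 496*64+64."""
        model = build_1d_cnn(CNN1DSpec(), input_length=65)
        counts = model.layer_param_counts()
        assert counts["conv1d(16x3)"] == 64
        assert counts["dense(64)"] == 496 * 64 + 64 == 31808
        assert model.layers[-1].units == 1

    def test_1d_conv_params_independent_of_length(self):
        for n in (10, 65, 200):
            model = build_1d_cnn(CNN1DSpec(), input_length=n)
            assert model.layer_param_counts()["conv1d(16x3)"] == 64

    def test_1d_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="input_length"):
            build_1d_cnn(CNN1DSpec(), input_length=3)

    def test_2d_parameter_arithmetic(self):
        """conv 3x3x3x16+16 = 448 params; 224 -> conv 222 -> pool 111 ->
        flatten 197136."""
        model = build_2d_cnn()
        counts = model.layer_param_counts()
        assert counts["conv2d(16x3x3)"] == 448
        assert counts["dense(64)"] == 197136 * 64 + 64
        out = model.forward(np.zeros((1, 224, 224, 3), dtype=np.float32))
        assert out.shape == (1, 1)

    def test_2d_wrong_input_shape_rejected(self):
        model = build_2d_cnn()
        with pytest.raises(ValueError, match="input shape"):
            model.forward(np.zeros((1, 100, 100, 3), dtype=np.float32))

    def test_architecture_parity(self):
        """The 1-D and 2-D models share the block structure
        conv-relu-pool-flatten-dense64-dropout-dense1."""
        m1 = build_1d_cnn(CNN1DSpec(), input_length=65)
        m2 = build_2d_cnn()
        kinds1 = [n.split("(")[0] for n in m1.layer_names]
        kinds2 = [n.split("(")[0] for n in m2.layer_names]
        assert kinds1 == ["conv1d", "relu", "maxpool1d", "flatten",
                          "dense", "relu", "dropout", "dense"]
        assert kinds2 == ["conv2d", "relu", "maxpool2d", "flatten",
                          "dense", "relu", "dropout", "dense"]
        assert [k.replace("1d", "").replace("2d", "") for k in kinds1] == [
            k.replace("1d", "").replace("2d", "") for k in kinds2
        ]


class TestTraining:
    def _toy_problem(self, n=32, length=20, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, length, 1)).astype(np.float32)
        y = 50.0 * X.mean(axis=(1, 2)) + 10.0
        return X, y.astype(np.float32)

    def test_lr_trace_non_increasing_with_floor(self):
        X, y = self._toy_problem()
        model = build_1d_cnn(CNN1DSpec(), input_length=20)
        cfg = TrainConfig.for_1d(epochs_max=40, lr_reduce_patience=2,
                                 early_stop_patience=40, lr_min=1e-6, seed=0)
        hist = train_model(model, (X, y), (X[:8], y[:8]), cfg)
        lrs = np.array(hist.lr)
        assert np.all(np.diff(lrs) <= 0)
        assert lrs.min() >= 1e-6
        assert hist.n_epochs <= 40

    def test_restore_best_weights(self):
        X, y = self._toy_problem(seed=1)
        model = build_1d_cnn(CNN1DSpec(), input_length=20, seed=1)
        cfg = TrainConfig.for_1d(epochs_max=30, seed=1)
        hist = train_model(model, (X, y), (X[:8], y[:8]), cfg)
        restored_val = float(np.mean((predict_cnn(model, X[:8]) - y[:8]) ** 2))
        assert restored_val == pytest.approx(min(hist.val_loss), rel=1e-5)

    def test_empty_validation_rejected(self):
        X, y = self._toy_problem()
        model = build_1d_cnn(CNN1DSpec(), input_length=20)
        with pytest.raises(ValueError, match="validation"):
            train_model(model, (X, y), (X[:0], y[:0]), TrainConfig.for_1d())

    def test_inference_deterministic(self):
        X, y = self._toy_problem()
        model = build_1d_cnn(CNN1DSpec(), input_length=20)
        np.testing.assert_array_equal(predict_cnn(model, X), predict_cnn(model, X))

    def test_seeded_training_reproducible(self):
        X, y = self._toy_problem(seed=2)
        h = []
        for _ in range(2):
            model = build_1d_cnn(CNN1DSpec(), input_length=20, seed=3)
            cfg = TrainConfig.for_1d(epochs_max=5, seed=3)
            h.append(train_model(model, (X, y), (X[:8], y[:8]), cfg))
        assert h[0].loss == h[1].loss
        assert h[0].val_loss == h[1].val_loss

    def test_1d_capacity_memorizes_noiseless_study(self, noiseless_rank2_study):
        """The 1-D network can drive training MSE below 1 (%^2) on the
        noiseless desk-scale study slice (memorization check)."""
        from eemkit.regression import extract_slice, spectra_to_matrix

        spectra = [extract_slice(s, 450.0) for s in noiseless_rank2_study]
        X, y = spectra_to_matrix(spectra)
        Xs, _, _, _ = zscore_fit_apply(X)
        Xc = spectra_to_cnn_input(Xs)
        model = build_1d_cnn(CNN1DSpec(), input_length=X.shape[1], seed=0)
        cfg = TrainConfig.for_1d(epochs_max=600, early_stop_patience=600,
                                 lr_reduce_patience=600, seed=0)
        hist = train_model(model, (Xc, y.astype(np.float32)), (Xc, y.astype(np.float32)), cfg)
        assert min(hist.val_loss) < 1.0


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Spot-check analytic gradients of the full 1-D block against
        central finite differences."""
        rng = np.random.default_rng(0)
        model = build_1d_cnn(CNN1DSpec(filters=2, dense_units=4), input_length=8, seed=0)
        # drop the dropout layer's randomness by eval-mode forward in loss
        X = rng.random((3, 8, 1)).astype(np.float32)
        y = rng.random(3).astype(np.float32)

        def loss():
            pred = model.forward(X.astype(np.float64), training=False).ravel()
            return float(np.mean((pred - y) ** 2))

        pred = model.forward(X, training=False).ravel()
        dout = (2.0 * (pred - y) / len(y)).astype(np.float32)[:, None]
        model.backward(dout)
        for p, g in zip(model.params, model.grads):
            flat_p = p.ravel()
            flat_g = g.ravel()
            for idx in rng.choice(flat_p.size, size=min(3, flat_p.size), replace=False):
                old = flat_p[idx]
                eps = 1e-3
                flat_p[idx] = old + eps
                up = loss()
                flat_p[idx] = old - eps
                down = loss()
                flat_p[idx] = old
                fd = (up - down) / (2 * eps)
                assert flat_g[idx] == pytest.approx(fd, rel=0.05, abs=1e-4)

    def test_images_to_array_roundtrip(self):
        imgs = [ContourImage(pixels=np.zeros((4, 4, 3), dtype=np.float32),
                             adulteration_pct=p) for p in (0.0, 50.0)]
        X, y = images_to_array(imgs)
        assert X.shape == (2, 4, 4, 3)
        np.testing.assert_array_equal(y, [0.0, 50.0])
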