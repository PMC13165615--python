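"""CNN regression on emission slices (1-D) and EEM contour images (2-D).

The 1-D model consumes z-score-standardized emission spectra; the 2-D model
consumes filled-contour renderings of globally normalized EEMs (512 px
intermediate, resized to 224 x 224 RGB, pixel values in [0, 1]).  Both share
one lightweight block: conv(16) -> ReLU -> maxpool -> flatten -> dense(64,
ReLU) -> dropout(0.2) -> dense(1, linear), trained with Adam on MSE, early
stopping (patience 20, best weights restored) and reduce-on-plateau LR
scheduling, mirroring the PLSR split and augmentation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .nn import (
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    MaxPool2D,
    ReLU,
    Sequential,
    TrainHistory,
    fit_regressor,
)
from .preprocess import NormalizedEEM

__all__ = [
    "CNN1DSpec",
    "CNN2DSpec",
    "TrainConfig",
    "ImageAugmentParams",
    "ContourImage",
    "zscore_fit_apply",
    "render_contour",
    "augment_matrices_for_images",
    "build_1d_cnn",
    "build_2d_cnn",
    "train_model",
    "predict_cnn",
]


@dataclass(frozen=True)
class CNN1DSpec:
    filters: int = 16
    kernel: int = 3
    pool: int = 2
    dense_units: int = 64
    dropout: float = 0.2


@dataclass(frozen=True)
class CNN2DSpec:
    filters: int = 16
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    dense_units: int = 64
    dropout: float = 0.2
    input_px: int = 224
    channels: int = 3


@dataclass(frozen=True)
class TrainConfig:
    """Shared training schedule; learning rate differs per architecture
    (1-D: 1e-3, 2-D: 5e-4)."""

    lr: float = 1e-3
    epochs_max: int = 300
    batch_size: int = 16
    early_stop_patience: int = 20
    restore_best: bool = True
    lr_reduce_factor: float = 0.5
    lr_reduce_patience: int = 10
    lr_min: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lr_min <= self.lr:
            raise ValueError("require 0 < lr_min <= lr")
        if self.early_stop_patience <= 0 or self.lr_reduce_patience <= 0:
            raise ValueError("patience counts must be positive")

    @classmethod
    def for_1d(cls, **kw) -> "TrainConfig":
        kw.setdefault("lr", 1e-3)
        return cls(**kw)

    @classmethod
    def for_2d(cls, **kw) -> "TrainConfig":
        kw.setdefault("lr", 5e-4)
        return cls(**kw)


@dataclass(frozen=True)
class ImageAugmentParams:
    """Hybrid matrix augmentation for the image pipeline: amplitude scaling
    U(0.85, 1.15) plus i.i.d. Gaussian noise with sigma ~ U(1.0, 5.0) in
    0-255 intensity units, applied before rendering."""

    amplitude_range: tuple[float, float] = (0.85, 1.15)
    noise_sigma_range: tuple[float, float] = (1.0, 5.0)
    copies: int = 9
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_range[0] > self.amplitude_range[1]:
            raise ValueError("amplitude_range must be ordered")
        if self.noise_sigma_range[0] > self.noise_sigma_range[1]:
            raise ValueError("noise_sigma_range must be ordered")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass(frozen=True)
class ContourImage:
    """Rendered EEM image, pixel values in [0, 1]."""

    pixels: np.ndarray
    sample_id: str = ""
    adulteration_pct: float = 0.0
    augmented: bool = False

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)


def zscore_fit_apply(
    train: np.ndarray, *others: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, np.ndarray]:
    """Per-wavelength z-score standardization fit on the training matrix.

    Returns the standardized training set, the other sets transformed with
    the frozen training statistics, and (mean, sd).  The sd is floored at
    1e-12 so constant columns map to zero.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need at least two training spectra")
    mean = train.mean(axis=0)
    sd = np.maximum(train.std(axis=0), 1e-12)
    out_others = [(np.asarray(o, dtype=float) - mean) / sd for o in others]
    return (train - mean) / sd, out_others, mean, sd


def render_contour(
    norm: NormalizedEEM,
    render_px: int = 512,
    out_px: int = 224,
    n_levels: int = 16,
    cmap: str = "viridis",
) -> ContourImage:
    """Deterministic raster filled-contour rendering of a normalized EEM.

    The matrix is bilinearly upsampled to ``render_px`` square, quantized
    into ``n_levels`` fixed intensity bands over [0, 255] (the filled
    contour), colored with a fixed colormap LUT and resized to ``out_px``
    square RGB with values scaled to [0, 1].
    """
    values = np.asarray(norm.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values cannot be rendered")
    values = np.clip(values, 0.0, 255.0)
    big = resize(values, (render_px, render_px), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    bands = np.clip((big / 256.0 * n_levels).astype(int), 0, n_levels - 1)
    lut = colormaps[cmap](np.linspace(0.0, 1.0, n_levels))[:, :3]
    rgb = lut[bands]
    small = resize(rgb, (out_px, out_px), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    return ContourImage(
        pixels=np.clip(small, 0.0, 1.0).astype(np.float32),
        sample_id=norm.sample_id,
        adulteration_pct=norm.adulteration_pct,
        augmented=norm.augmented,
    )


def augment_matrices_for_images(
    train_matrices: list[NormalizedEEM], params: ImageAugmentParams
) -> list[NormalizedEEM]:
    """Originals plus perturbed copies (amplitude scale + Gaussian noise,
    clipped at zero).  Training partition only; copies keep their label and
    are flagged ``augmented``."""
    rng = np.random.default_rng(params.seed)
    out = list(train_matrices)
    low, high = params.amplitude_range
    slo, shi = params.noise_sigma_range
    for m in train_matrices:
        for _ in range(params.copies):
            amp = rng.uniform(low, high)
            sigma = rng.uniform(slo, shi)
            noisy = amp * m.values
            if sigma > 0:
                noisy = noisy + rng.normal(0.0, sigma, size=noisy.shape)
            out.append(replace(m, values=np.clip(noisy, 0.0, None), augmented=True))
    return out


def build_1d_cnn(spec: CNN1DSpec, input_length: int, seed: int = 0) -> Sequential:
    """conv(16, k3) -> ReLU -> maxpool(2) -> flatten -> dense(64, ReLU) ->
    dropout(0.2) -> dense(1, linear); input (length, 1 channel)."""
    if input_length <= spec.kernel:
        raise ValueError(f"input_length must exceed the kernel size {spec.kernel}")
    return Sequential(
        [
            Conv1D(spec.filters, spec.kernel),
            ReLU(),
            MaxPool1D(spec.pool),
            Flatten(),
            Dense(spec.dense_units),
            ReLU(),
            Dropout(spec.dropout),
            Dense(1),
        ],
        input_shape=(input_length, 1),
        seed=seed,
    )


def build_2d_cnn(spec: CNN2DSpec | None = None, seed: int = 0) -> Sequential:
    """Same block in 2-D on 224 x 224 x 3 contour images."""
    spec = spec or CNN2DSpec()
    return Sequential(
        [
            Conv2D(spec.filters, spec.kernel),
            ReLU(),
            MaxPool2D(spec.pool),
            Flatten(),
            Dense(spec.dense_units),
            ReLU(),
            Dropout(spec.dropout),
            Dense(1),
        ],
        input_shape=(spec.input_px, spec.input_px, spec.channels),
        seed=seed,
    )


def train_model(
    model: Sequential,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> TrainHistory:
    """Train with the shared schedule; returns the per-epoch history with
    best weights restored in-place on the model."""
    X, y = train
    Xv, yv = val
    return fit_regressor(
        model,
        X,
        y,
        Xv,
        yv,
        lr=config.lr,
        epochs_max=config.epochs_max,
        batch_size=config.batch_size,
        early_stop_patience=config.early_stop_patience,
        lr_reduce_factor=config.lr_reduce_factor,
        lr_reduce_patience=config.lr_reduce_patience,
        lr_min=config.lr_min,
        restore_best=config.restore_best,
        seed=config.seed,
    )


def predict_cnn(model: Sequential, inputs: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout inactive)."""
    return model.predict(inputs)


def spectra_to_cnn_input(X: np.ndarray) -> np.ndarray:
    """Append the single-channel axis the 1-D CNN expects."""
    X = np.asarray(X, dtype=np.float32)
    return X[:, :, None]


def images_to_array(images: list[ContourImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack contour images into (X, y) arrays."""
    X = np.stack([im.pixels for im in images])
    y = np.array([im.adulteration_pct for im in images], dtype=np.float32)
    return X, y
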