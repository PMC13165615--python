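"""Scatter removal and normalization for EEM landscapes.

The cleaning protocol masks first-order Rayleigh scatter within +/-25 nm of
the excitation wavelength and second-order scatter within +/-20 nm of twice
the excitation wavelength, reconstructs the excised region by 2-D cubic
interpolation, smooths with a Gaussian filter (sigma 1.5 grid units) and
clips negative intensities.  A separate zero-filling path feeds PARAFAC,
and global-maximum normalization rescales a dataset to the 8-bit range for
image rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata
from scipy.ndimage import gaussian_filter

from .synthetic import EEMDataset, EEMGrid, EEMSample

__all__ = [
    "PreprocessConfig",
    "ScatterMask",
    "NormalizedEEM",
    "build_scatter_mask",
    "interpolate_masked",
    "smooth_and_clip",
    "normalize_global",
    "zero_fill_scatter",
    "preprocess_sample",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Scatter-excision bandwidths (nm half-widths) and smoothing width.

    ``gaussian_sigma`` is in grid-index units, the usual image-filter
    convention.  ``raman_bw_nm`` adds an optional extra band below the
    first-order ridge; it is off (None) by default because the +/-25 nm
    first-order band already covers the Raman region at this resolution.
    """

    first_order_bw_nm: float = 25.0
    second_order_bw_nm: float = 20.0
    gaussian_sigma: float = 1.5
    clip_negative: bool = True
    raman_bw_nm: float | None = None

    def __post_init__(self):
        if self.first_order_bw_nm <= 0 or self.second_order_bw_nm <= 0:
            raise ValueError("bandwidths must be positive")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


@dataclass(frozen=True)
class ScatterMask:
    """Boolean matrix (excitation x emission); True marks scatter pixels."""

    mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class NormalizedEEM:
    """EEM rescaled to the dataset-wide [0, 255] range."""

    grid: EEMGrid
    values: np.ndarray
    sample_id: str = ""
    adulteration_pct: float = 0.0
    augmented: bool = False


def build_scatter_mask(grid: EEMGrid, config: PreprocessConfig | None = None) -> ScatterMask:
    """Mark grid points within the first-order band |em - ex| <= bw1 or the
    second-order band |em - 2*ex| <= bw2 (wavelengths only; intensity-free)."""
    config = config or PreprocessConfig()
    ex = grid.excitation_nm[:, None]
    em = grid.emission_nm[None, :]
    mask = (np.abs(em - ex) <= config.first_order_bw_nm) | (
        np.abs(em - 2.0 * ex) <= config.second_order_bw_nm
    )
    if config.raman_bw_nm is not None:
        # Raman shift of water: ~3400 cm^-1 red of the excitation line.
        raman_center = 1.0 / (1.0 / ex - 3400e-7)
        mask |= np.abs(em - raman_center) <= config.raman_bw_nm
    return ScatterMask(mask=mask)


def interpolate_masked(sample: EEMSample, mask: ScatterMask) -> EEMSample:
    """Replace masked values by 2-D cubic interpolation over unmasked points.

    Cubic interpolation is undefined outside the convex hull of the source
    points; those pixels fall back to nearest-neighbor extrapolation so the
    output is finite everywhere.  Unmasked values are left untouched.
    """
    m = mask.mask
    if m.shape != sample.intensity.shape:
        raise ValueError("mask shape does not match sample")
    if not m.any():
        return sample.with_intensity(sample.intensity.copy())
    if m.all():
        raise ValueError("nothing to interpolate from: mask covers the whole matrix")

    ex = sample.grid.excitation_nm
    em = sample.grid.emission_nm
    exg, emg = np.meshgrid(ex, em, indexing="ij")
    known = ~m
    pts = np.column_stack([exg[known], emg[known]])
    vals = sample.intensity[known]
    targets = np.column_stack([exg[m], emg[m]])

    filled = griddata(pts, vals, targets, method="cubic")
    bad = ~np.isfinite(filled)
    if bad.any():
        filled[bad] = griddata(pts, vals, targets[bad], method="nearest")

    out = sample.intensity.copy()
    out[m] = filled
    return sample.with_intensity(out)


def smooth_and_clip(sample: EEMSample, config: PreprocessConfig | None = None) -> EEMSample:
    """Gaussian-smooth (reflective boundaries, so constants are preserved)
    then set negative intensities to zero."""
    config = config or PreprocessConfig()
    out = gaussian_filter(sample.intensity, sigma=config.gaussian_sigma, mode="reflect")
    if config.clip_negative:
        out = np.clip(out, 0.0, None)
    return sample.with_intensity(out)


def zero_fill_scatter(sample: EEMSample, mask: ScatterMask) -> EEMSample:
    """Set masked entries to zero (the PARAFAC input path)."""
    m = mask.mask
    if m.shape != sample.intensity.shape:
        raise ValueError("mask shape does not match sample")
    out = sample.intensity.copy()
    out[m] = 0.0
    return sample.with_intensity(out)


def preprocess_sample(sample: EEMSample, mask: ScatterMask,
                      config: PreprocessConfig | None = None) -> EEMSample:
    """Full cleaning sequence: mask -> interpolate -> smooth -> clip."""
    return smooth_and_clip(interpolate_masked(sample, mask), config)


def normalize_global(dataset: EEMDataset, global_max: float | None = None) -> list[NormalizedEEM]:
    """Scale every matrix by the dataset-wide maximum onto [0, 255].

    ``global_max`` may be supplied explicitly (e.g. the calibration-set
    maximum, so prediction samples are scaled with training statistics).
    """
    gmax = dataset.global_max if global_max is None else float(global_max)
    if gmax <= 0:
        raise ValueError("degenerate dataset: global maximum is not positive")
    return [
        NormalizedEEM(
            grid=s.grid,
            values=s.intensity / gmax * 255.0,
            sample_id=s.sample_id,
            adulteration_pct=s.adulteration_pct,
        )
        for s in dataset.samples
    ]
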