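"""Emission-slice extraction and PLSR calibration.

One-dimensional emission spectra are taken at fixed excitation wavelengths
(290 nm tryptophan, 330 nm vitamin A/retinol, 450 nm riboflavin), optionally
corrected by multiplicative scatter correction (MSC) or a Savitzky-Golay
first derivative (SG1), expanded by a x9 spectral augmentation (offset,
slope and multiplicative perturbations) and regressed on the adulteration
level with partial least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .synthetic import EEMSample

__all__ = [
    "EmissionSpectrum",
    "AugmentationParams",
    "PLSRModel",
    "extract_slice",
    "msc_correct",
    "sg_first_derivative",
    "augment_spectra",
    "spectra_to_matrix",
    "fit_plsr",
    "predict_plsr",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """1-D emission slice at a fixed excitation wavelength."""

    emission_nm: np.ndarray
    intensities: np.ndarray
    excitation_nm: float
    adulteration_pct: float
    augmented: bool = False

    def __post_init__(self):
        em = np.asarray(self.emission_nm, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if em.shape != y.shape:
            raise ValueError("wavelength and intensity lengths disagree")
        object.__setattr__(self, "emission_nm", em)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class AugmentationParams:
    """Spectral augmentation: x' = m*x + b*1 + s*lambda~ with lambda~ the
    wavelength axis rescaled to [-1, 1].

    ``factor`` counts augmented copies per original (9 copies + the original
    gives the x10 expansion 63 -> 630 that the x9 scheme denotes).  Offset
    and slope magnitudes are fractions of each spectrum's standard
    deviation.
    """

    factor: int = 9
    offset_scale: float = 0.1
    slope_scale: float = 0.1
    multiplicative_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        if self.factor < 0:
            raise ValueError("factor must be >= 0")
        low, high = self.multiplicative_range
        if low > high:
            raise ValueError("multiplicative_range must be ordered")


def extract_slice(sample: EEMSample, excitation_nm: float) -> EmissionSpectrum:
    """Row of the EEM at the requested excitation wavelength."""
    ex = sample.grid.excitation_nm
    idx = np.where(np.isclose(ex, excitation_nm, atol=1e-9))[0]
    if idx.size == 0:
        nearest = ex[np.argsort(np.abs(ex - excitation_nm))[:2]]
        raise ValueError(
            f"excitation {excitation_nm} nm is not on the grid; "
            f"nearest grid wavelengths: {sorted(nearest.tolist())}"
        )
    return EmissionSpectrum(
        emission_nm=sample.grid.emission_nm.copy(),
        intensities=sample.intensity[idx[0]].copy(),
        excitation_nm=float(excitation_nm),
        adulteration_pct=sample.adulteration_pct,
    )


def msc_correct(
    spectra: list[EmissionSpectrum], reference: np.ndarray | None = None
) -> tuple[list[EmissionSpectrum], np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference, x ~ a + b*ref, and
    corrected to (x - a) / b.  The reference defaults to the mean of the
    input (calibration) spectra and is returned so prediction spectra can
    be corrected with the frozen calibration reference.
    """
    if reference is None:
        if len(spectra) < 2:
            raise ValueError("need at least two spectra to form an MSC reference")
        reference = np.mean([s.intensities for s in spectra], axis=0)
    reference = np.asarray(reference, dtype=float)
    if np.std(reference) < 1e-12:
        raise ValueError("degenerate spectrum: constant MSC reference has no slope")
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    corrected = []
    for s in spectra:
        x = s.intensities
        b = float(ref_c @ (x - x.mean())) / denom
        if abs(b) < 1e-12:
            raise ValueError("degenerate spectrum: fitted MSC slope is ~0")
        a = float(x.mean() - b * reference.mean())
        corrected.append(replace(s, intensities=(x - a) / b))
    return corrected, reference


def sg_first_derivative(
    spectrum: EmissionSpectrum, window: int = 11, polyorder: int = 2
) -> EmissionSpectrum:
    """Savitzky-Golay first derivative in intensity-per-grid-step units."""
    n = spectrum.intensities.size
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not window > polyorder >= 1:
        raise ValueError("require window > polyorder >= 1")
    if window >= n:
        raise ValueError(f"window {window} must be smaller than spectrum length {n}")
    deriv = savgol_filter(spectrum.intensities, window, polyorder, deriv=1, delta=1.0)
    return replace(spectrum, intensities=deriv)


def augment_spectra(
    spectra: list[EmissionSpectrum], params: AugmentationParams
) -> list[EmissionSpectrum]:
    """Originals plus ``params.factor`` perturbed copies per original.

    Copies carry the original label, are marked ``augmented=True`` and are
    reproducible for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    out = list(spectra)
    low, high = params.multiplicative_range
    for s in spectra:
        x = s.intensities
        std = float(np.std(x))
        lam = s.emission_nm
        span = lam[-1] - lam[0]
        lam_norm = (2.0 * (lam - lam[0]) / span - 1.0) if span > 0 else np.zeros_like(lam)
        for _ in range(params.factor):
            m = rng.uniform(low, high)
            b = rng.uniform(-params.offset_scale, params.offset_scale) * std
            slope = rng.uniform(-params.slope_scale, params.slope_scale) * std
            out.append(replace(s, intensities=m * x + b + slope * lam_norm, augmented=True))
    return out


def spectra_to_matrix(spectra: list[EmissionSpectrum]) -> tuple[np.ndarray, np.ndarray]:
    """Stack spectra into (X, y) arrays for modeling."""
    X = np.stack([s.intensities for s in spectra])
    y = np.array([s.adulteration_pct for s in spectra])
    return X, y


@dataclass
class PLSRModel:
    """Fitted PLSR: prediction = (x - x_mean) @ coefficients + y_mean."""

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    cv_rmse: np.ndarray | None = None


def _fit_sklearn_pls(X: np.ndarray, y: np.ndarray, k: int) -> PLSRegression:
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(X, y)
    return pls


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_latent: int | None = None,
    max_latent: int = 15,
    cv_folds: int = 10,
    seed: int = 0,
) -> PLSRModel:
    """Latent-variable regression of the label on spectra.

    When ``n_latent`` is not given it is chosen by k-fold cross-validated
    RMSE on the calibration set (k = 10, capped at 15 latent variables),
    with a one-standard-error tie-break toward fewer components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two calibration samples")
    if np.std(y) < 1e-12:
        raise ValueError("constant response: nothing to regress")
    k_max = min(max_latent, n - 1, p)

    cv_rmse_mean = None
    if n_latent is None:
        folds = min(cv_folds, n)
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        errs = np.zeros((k_max, folds))
        for j, (tr, te) in enumerate(kf.split(X)):
            for k in range(1, k_max + 1):
                k_eff = min(k, len(tr) - 1)
                pls = _fit_sklearn_pls(X[tr], y[tr], k_eff)
                pred = pls.predict(X[te]).ravel()
                errs[k - 1, j] = np.sqrt(np.mean((pred - y[te]) ** 2))
        cv_rmse_mean = errs.mean(axis=1)
        best = int(np.argmin(cv_rmse_mean))
        se = errs[best].std(ddof=1) / np.sqrt(folds) if folds > 1 else 0.0
        n_latent = 1 + int(np.argmax(cv_rmse_mean <= cv_rmse_mean[best] + se))
    if not 1 <= n_latent <= k_max:
        raise ValueError(f"n_latent must lie in [1, {k_max}]")

    pls = _fit_sklearn_pls(X, y, n_latent)
    return PLSRModel(
        n_latent=n_latent,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_,
        coefficients=pls.coef_.ravel(),
        cv_rmse=cv_rmse_mean,
    )


def predict_plsr(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Deterministic linear prediction."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"wavelength count {X.shape[1]} does not match training ({model.x_mean.size})"
        )
    return (X - model.x_mean) @ model.coefficients + model.y_mean
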