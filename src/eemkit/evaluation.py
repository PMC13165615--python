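"""Stratified splitting and the regression metric suite.

Reports follow the chemometric convention: calibration (C), internal
validation (V) and independent prediction (P) streams, each summarized by
R^2 and RMSE, plus the residual predictive deviation (RPD = sd(reference) /
RMSEP; > 3 indicates practical utility) and a multivariate limit of
detection (LOD = factor x RMSE, factor 3.3 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .synthetic import EEMDataset

__all__ = [
    "SplitSpec",
    "PredictionSet",
    "MetricsConfig",
    "RegressionReport",
    "stratified_split",
    "stratified_split_indices",
    "r_squared",
    "rmse",
    "rpd",
    "lod",
    "assemble_report",
    "round_half_up",
]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified calibration/prediction split by adulteration level."""

    calibration_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ValueError("calibration_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class PredictionSet:
    """Paired reference/predicted adulteration levels (% v/v)."""

    y_reference: np.ndarray
    y_predicted: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.y_reference, dtype=float).ravel()
        pred = np.asarray(self.y_predicted, dtype=float).ravel()
        if ref.shape != pred.shape:
            raise ValueError("reference and predicted vectors must have equal length")
        if ref.size < 2:
            raise ValueError("need at least two samples")
        object.__setattr__(self, "y_reference", ref)
        object.__setattr__(self, "y_predicted", pred)

    @property
    def n(self) -> int:
        return self.y_reference.size

    @property
    def mean_reference(self) -> float:
        return float(self.y_reference.mean())


@dataclass(frozen=True)
class MetricsConfig:
    """LOD factor (default 3.3, the ICH-style 3.3*sigma multiplier; set 3.0
    for the literal 3x convention) and which RMSE stream feeds the LOD."""

    lod_factor: float = 3.3
    lod_rmse_source: str = "validation"

    def __post_init__(self):
        if self.lod_factor <= 0:
            raise ValueError("lod_factor must be positive")
        if self.lod_rmse_source not in ("validation", "prediction"):
            raise ValueError("lod_rmse_source must be 'validation' or 'prediction'")


@dataclass
class RegressionReport:
    """One table row: metrics for a single model configuration."""

    descriptor: str
    R2C: float | None
    RMSEC: float | None
    R2V: float | None
    RMSEV: float | None
    R2P: float
    RMSEP: float
    RPD: float
    LOD: float

    COLUMNS = ("R2C", "RMSEC", "R2V", "RMSEV", "R2P", "RMSEP", "RPD", "LOD")

    def to_row(self, display: bool = True) -> dict:
        row = {"model": self.descriptor}
        for c in self.COLUMNS:
            v = getattr(self, c)
            row[c] = round_half_up(v, 2) if (display and v is not None and np.isfinite(v)) else v
        return row


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (the tabulation convention;
    float banker's rounding would print 11.055 -> 11.05 instead of 11.06).
    The value is pre-rounded to ndigits+2 decimals so that binary float
    artifacts (e.g. 14.354999...) do not flip the half-up decision."""
    q = Decimal(1).scaleb(-ndigits)
    pre = Decimal(repr(round(float(value), ndigits + 2)))
    return float(pre.quantize(q, rounding=ROUND_HALF_UP))


def stratified_split_indices(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per level, round(fraction * n_level) indices go to calibration and
    the rest to prediction; seeded, disjoint, both partitions non-empty."""
    labels = np.asarray(labels, dtype=float)
    rng = np.random.default_rng(spec.seed)
    cal, pred = [], []
    for level in np.unique(labels):
        idx = np.flatnonzero(labels == level)
        if idx.size < 2:
            raise ValueError(
                f"level {level:g} has {idx.size} replicate(s); need >= 2 to stratify"
            )
        idx = rng.permutation(idx)
        n_cal = int(round(spec.calibration_fraction * idx.size))
        n_cal = min(max(n_cal, 1), idx.size - 1)
        cal.extend(idx[:n_cal])
        pred.extend(idx[n_cal:])
    return np.sort(np.array(cal)), np.sort(np.array(pred))


def stratified_split(dataset: EEMDataset, spec: SplitSpec) -> tuple[EEMDataset, EEMDataset]:
    cal_idx, pred_idx = stratified_split_indices(dataset.labels, spec)
    return dataset.subset(cal_idx), dataset.subset(pred_idx)


def r_squared(p: PredictionSet, printed_form: bool = False) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    The standard form takes SS_tot about the reference values; the
    ``printed_form`` variant uses deviations of the *predicted* values from
    the reference mean (available for comparison only).
    """
    res = float(np.sum((p.y_predicted - p.y_reference) ** 2))
    if printed_form:
        tot = float(np.sum((p.mean_reference - p.y_predicted) ** 2))
    else:
        tot = float(np.sum((p.y_reference - p.mean_reference) ** 2))
    if tot <= 0:
        raise ValueError("zero reference variance: R^2 undefined")
    return 1.0 - res / tot


def rmse(p: PredictionSet) -> float:
    """Root mean square error, sqrt(sum((y_p - y_a)^2) / n)."""
    return float(np.sqrt(np.mean((p.y_predicted - p.y_reference) ** 2)))


def rpd(p: PredictionSet, rmse_p: float | None = None) -> float:
    """Residual predictive deviation: sd(reference, n-1) / RMSEP."""
    sd = float(np.std(p.y_reference, ddof=1))
    if sd <= 0:
        raise ValueError("constant reference vector: RPD undefined")
    if rmse_p is None:
        rmse_p = rmse(p)
    if rmse_p == 0:
        warnings.warn("zero RMSE: RPD reported as infinity", stacklevel=2)
        return float("inf")
    return sd / rmse_p


def lod(rmse_value: float, config: MetricsConfig | None = None) -> float:
    """Multivariate limit of detection: lod_factor x RMSE (% v/v)."""
    if rmse_value < 0:
        raise ValueError("RMSE must be non-negative")
    config = config or MetricsConfig()
    return config.lod_factor * float(rmse_value)


def assemble_report(
    calibration_fit: PredictionSet,
    validation_fit: PredictionSet | None,
    prediction_fit: PredictionSet,
    config: MetricsConfig | None = None,
    descriptor: str = "",
) -> RegressionReport:
    """Compute the full metric row for one model.

    The LOD uses the validation RMSE when a validation stream exists (and
    the config names it), otherwise the prediction RMSE.
    """
    if prediction_fit is None:
        raise ValueError("prediction set is required")
    config = config or MetricsConfig()
    rmsec = rmse(calibration_fit)
    rmsep = rmse(prediction_fit)
    if validation_fit is not None:
        r2v, rmsev = r_squared(validation_fit), rmse(validation_fit)
    else:
        r2v, rmsev = None, None
    lod_rmse = rmsev if (config.lod_rmse_source == "validation" and rmsev is not None) else rmsep
    return RegressionReport(
        descriptor=descriptor,
        R2C=r_squared(calibration_fit),
        RMSEC=rmsec,
        R2V=r2v,
        RMSEV=rmsev,
        R2P=r_squared(prediction_fit),
        RMSEP=rmsep,
        RPD=rpd(prediction_fit, rmsep),
        LOD=lod(lod_rmse, config),
    )


def reports_to_frame(reports: list[RegressionReport], display: bool = True) -> pd.DataFrame:
    """Tabulate reports with the standard 8 metric columns."""
    return pd.DataFrame([r.to_row(display=display) for r in reports])
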