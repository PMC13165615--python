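"""End-to-end experiment orchestration.

One seeded run simulates the concentration-series study, cleans the EEMs,
fits PARAFAC with model-order selection, and trains/evaluates every
regression family (PLSR at three excitations x three preprocessings x two
augmentation states, 1-D CNN per excitation, 2-D CNN with and without image
augmentation) on a single shared stratified calibration/prediction split,
then tabulates the metric reports.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .cnn import (
    CNN1DSpec,
    CNN2DSpec,
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
from .evaluation import (
    MetricsConfig,
    PredictionSet,
    RegressionReport,
    SplitSpec,
    assemble_report,
    reports_to_frame,
    stratified_split_indices,
)
from .parafac import EEMTensor, component_scores_vs_level, fit_parafac, select_components
from .preprocess import PreprocessConfig, build_scatter_mask, normalize_global, preprocess_sample
from .regression import (
    AugmentationParams,
    EmissionSpectrum,
    augment_spectra,
    extract_slice,
    fit_plsr,
    msc_correct,
    predict_plsr,
    sg_first_derivative,
    spectra_to_matrix,
)
from .synthetic import EEMDataset, NoiseSpec, StudyDesign, generate_study

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment", "compare_models",
           "run_plsr_family", "run_cnn2d_family"]


@dataclass
class ExperimentConfig:
    """Every knob of one experiment; nested configs carry their own
    defaults, which reproduce the study design (9 levels x 10 replicates,
    70:30 split, x9 augmentation)."""

    design: StudyDesign = field(default_factory=StudyDesign)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    augmentation: AugmentationParams = field(default_factory=AugmentationParams)
    image_augment: ImageAugmentParams = field(default_factory=ImageAugmentParams)
    excitations: tuple[float, ...] = (290.0, 330.0, 450.0)
    pls_preprocessings: tuple[str, ...] = ("msc", "sg1", "raw")
    parafac_F_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    parafac_tol: float = 1e-6
    parafac_max_iter: int = 2000
    epochs_1d: int = 300
    epochs_2d: int = 300
    master_seed: int = 0


@dataclass
class RunManifest:
    """Record of one run: seeds, sizes, diagnostics and metric tables."""

    master_seed: int
    stage_seeds: dict
    version: str
    started_at: float
    finished_at: float | None = None
    n_samples: int = 0
    n_calibration: int = 0
    n_prediction: int = 0
    parafac_diagnostics: pd.DataFrame | None = None
    parafac_selected_F: int = 0
    score_table: pd.DataFrame | None = None
    pls_reports: list[RegressionReport] = field(default_factory=list)
    cnn1d_reports: list[RegressionReport] = field(default_factory=list)
    cnn2d_reports: list[RegressionReport] = field(default_factory=list)

    @property
    def all_reports(self) -> list[RegressionReport]:
        return [*self.pls_reports, *self.cnn1d_reports, *self.cnn2d_reports]

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "master_seed": self.master_seed,
            "stage_seeds": self.stage_seeds,
            "version": self.version,
            "started_at": self.started_at,
            "finished_at": self.finished_at,
            "n_samples": self.n_samples,
            "n_calibration": self.n_calibration,
            "n_prediction": self.n_prediction,
            "parafac_selected_F": self.parafac_selected_F,
        }
        (out / "manifest.json").write_text(json.dumps(meta, indent=1))
        if self.parafac_diagnostics is not None:
            self.parafac_diagnostics.to_csv(out / "parafac_diagnostics.csv", index=False)
        if self.score_table is not None:
            self.score_table.to_csv(out / "parafac_scores_vs_level.csv", index=False)
        for name, reports in (
            ("pls_reports", self.pls_reports),
            ("cnn1d_reports", self.cnn1d_reports),
            ("cnn2d_reports", self.cnn2d_reports),
        ):
            if reports:
                reports_to_frame(reports).to_csv(out / f"{name}.csv", index=False)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: adding a stage never shifts earlier streams."""
    return (int(master_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _apply_pls_preprocessing(
    method: str,
    cal: list[EmissionSpectrum],
    pred: list[EmissionSpectrum],
) -> tuple[list[EmissionSpectrum], list[EmissionSpectrum]]:
    """MSC/SG1/raw; MSC reference is learned on calibration only."""
    if method == "raw":
        return cal, pred
    if method == "msc":
        cal_c, ref = msc_correct(cal)
        pred_c, _ = msc_correct(pred, reference=ref)
        return cal_c, pred_c
    if method == "sg1":
        return [sg_first_derivative(s) for s in cal], [sg_first_derivative(s) for s in pred]
    raise ValueError(f"unknown preprocessing '{method}'")


def _cv_validation_set(X, y, n_latent, folds, seed) -> PredictionSet | None:
    """Internal-validation stream: out-of-fold predictions on the
    calibration set at the chosen latent dimension."""
    from sklearn.model_selection import KFold

    n = len(y)
    folds = min(folds, n)
    if folds < 2:
        return None
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(n)
    for tr, te in kf.split(X):
        k = min(n_latent, len(tr) - 1)
        m = fit_plsr(X[tr], y[tr], n_latent=k)
        pred[te] = predict_plsr(m, X[te])
    return PredictionSet(y_reference=y, y_predicted=pred)


def run_plsr_family(
    clean: EEMDataset,
    cal_idx: np.ndarray,
    pred_idx: np.ndarray,
    excitations=(290.0, 330.0, 450.0),
    preprocessings=("msc", "sg1", "raw"),
    augmentation: AugmentationParams | None = None,
    metrics: MetricsConfig | None = None,
    seed: int = 0,
) -> list[RegressionReport]:
    """All excitation x preprocessing x augmentation PLSR rows on the
    shared split (the 18-model comparison)."""
    augmentation = augmentation or AugmentationParams()
    metrics = metrics or MetricsConfig()
    reports = []
    for ex in excitations:
        cal = [extract_slice(clean.samples[i], ex) for i in cal_idx]
        pred = [extract_slice(clean.samples[i], ex) for i in pred_idx]
        for method in preprocessings:
            cal_p, pred_p = _apply_pls_preprocessing(method, cal, pred)
            for augmented in (False, True):
                train = cal_p
                if augmented:
                    aug_seed = stage_seed(seed, f"pls-aug-{ex}-{method}")
                    train = augment_spectra(cal_p, replace(augmentation, seed=aug_seed))
                X, y = spectra_to_matrix(train)
                model = fit_plsr(X, y, seed=stage_seed(seed, f"pls-cv-{ex}-{method}-{augmented}"))
                Xc, yc = spectra_to_matrix(cal_p)
                Xp, yp = spectra_to_matrix(pred_p)
                val = _cv_validation_set(
                    X, y, model.n_latent, 10, stage_seed(seed, f"pls-val-{ex}-{method}-{augmented}")
                )
                reports.append(
                    assemble_report(
                        PredictionSet(yc, predict_plsr(model, Xc)),
                        val,
                        PredictionSet(yp, predict_plsr(model, Xp)),
                        metrics,
                        descriptor=f"PLSR ex{ex:g} {method} {'a' if augmented else 'n-a'}",
                    )
                )
    return reports


def _fit_val_split(labels: np.ndarray, frac: float, seed: int):
    """Hold out ~frac of the calibration originals (stratified by level,
    used un-augmented) as the early-stopping validation stream."""
    spec = SplitSpec(calibration_fraction=1.0 - frac, seed=seed)
    return stratified_split_indices(labels, spec)


def run_cnn1d_family(
    clean: EEMDataset,
    cal_idx: np.ndarray,
    pred_idx: np.ndarray,
    excitations=(290.0, 330.0, 450.0),
    augmentation: AugmentationParams | None = None,
    metrics: MetricsConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> list[RegressionReport]:
    """1-D CNN per excitation on augmented, z-scored emission slices."""
    augmentation = augmentation or AugmentationParams()
    metrics = metrics or MetricsConfig()
    base_cfg = train_config or TrainConfig.for_1d()
    reports = []
    for ex in excitations:
        cal = [extract_slice(clean.samples[i], ex) for i in cal_idx]
        pred = [extract_slice(clean.samples[i], ex) for i in pred_idx]
        cal_labels = np.array([s.adulteration_pct for s in cal])
        fit_i, val_i = _fit_val_split(cal_labels, 0.2, stage_seed(seed, f"cnn1d-val-{ex}"))
        fit_spectra = [cal[i] for i in fit_i]
        val_spectra = [cal[i] for i in val_i]
        train = augment_spectra(
            fit_spectra, replace(augmentation, seed=stage_seed(seed, f"cnn1d-aug-{ex}"))
        )
        Xt, yt = spectra_to_matrix(train)
        Xv, yv = spectra_to_matrix(val_spectra)
        Xc, yc = spectra_to_matrix(cal)
        Xp, yp = spectra_to_matrix(pred)
        Xt_s, (Xv_s, Xc_s, Xp_s), _, _ = zscore_fit_apply(Xt, Xv, Xc, Xp)
        cfg = replace(base_cfg, seed=stage_seed(seed, f"cnn1d-train-{ex}"))
        model = build_1d_cnn(CNN1DSpec(), input_length=Xt.shape[1],
                             seed=stage_seed(seed, f"cnn1d-init-{ex}"))
        train_model(model, (spectra_to_cnn_input(Xt_s), yt), (spectra_to_cnn_input(Xv_s), yv), cfg)
        reports.append(
            assemble_report(
                PredictionSet(yc, predict_cnn(model, spectra_to_cnn_input(Xc_s))),
                None,
                PredictionSet(yp, predict_cnn(model, spectra_to_cnn_input(Xp_s))),
                replace(metrics, lod_rmse_source="prediction"),
                descriptor=f"1D-CNN ex{ex:g}",
            )
        )
    return reports


def run_cnn2d_family(
    clean: EEMDataset,
    cal_idx: np.ndarray,
    pred_idx: np.ndarray,
    image_augment: ImageAugmentParams | None = None,
    metrics: MetricsConfig | None = None,
    train_config: TrainConfig | None = None,
    augmented_states=(False, True),
    seed: int = 0,
    render_kwargs: dict | None = None,
) -> list[RegressionReport]:
    """2-D CNN on contour images, with and without matrix augmentation.

    Global-max normalization uses the calibration maximum only, so the
    prediction stream carries no statistic of its own.
    """
    image_augment = image_augment or ImageAugmentParams()
    metrics = metrics or MetricsConfig()
    base_cfg = train_config or TrainConfig.for_2d()
    render_kwargs = render_kwargs or {}

    cal_ds = clean.subset(cal_idx)
    pred_ds = clean.subset(pred_idx)
    gmax = cal_ds.global_max
    norm_cal = normalize_global(cal_ds, global_max=gmax)
    norm_pred = normalize_global(pred_ds, global_max=gmax)

    cal_labels = np.array([m.adulteration_pct for m in norm_cal])
    fit_i, val_i = _fit_val_split(cal_labels, 0.2, stage_seed(seed, "cnn2d-val"))
    fit_mats = [norm_cal[i] for i in fit_i]
    val_mats = [norm_cal[i] for i in val_i]

    img_cal = [render_contour(m, **render_kwargs) for m in norm_cal]
    img_val = [render_contour(m, **render_kwargs) for m in val_mats]
    img_pred = [render_contour(m, **render_kwargs) for m in norm_pred]
    Xc, yc = images_to_array(img_cal)
    Xv, yv = images_to_array(img_val)
    Xp, yp = images_to_array(img_pred)

    reports = []
    for augmented in augmented_states:
        mats = fit_mats
        if augmented:
            mats = augment_matrices_for_images(
                fit_mats, replace(image_augment, seed=stage_seed(seed, "cnn2d-aug"))
            )
        Xt, yt = images_to_array([render_contour(m, **render_kwargs) for m in mats])
        cfg = replace(base_cfg, seed=stage_seed(seed, f"cnn2d-train-{augmented}"))
        sample_px = Xt.shape[1]
        model = build_2d_cnn(CNN2DSpec(input_px=sample_px),
                             seed=stage_seed(seed, f"cnn2d-init-{augmented}"))
        train_model(model, (Xt, yt), (Xv, yv), cfg)
        reports.append(
            assemble_report(
                PredictionSet(yc, predict_cnn(model, Xc)),
                None,
                PredictionSet(yp, predict_cnn(model, Xp)),
                replace(metrics, lod_rmse_source="prediction"),
                descriptor=f"2D-CNN {'augmented' if augmented else 'non-augmented'}",
            )
        )
    return reports


def run_experiment(config: ExperimentConfig, output_dir=None) -> RunManifest:
    """Execute all stages on one shared split and tabulate every report."""
    seeds = {
        stage: stage_seed(config.master_seed, stage)
        for stage in ("simulate", "split", "parafac", "pls", "cnn1d", "cnn2d")
    }
    manifest = RunManifest(
        master_seed=config.master_seed,
        stage_seeds=seeds,
        version=__version__,
        started_at=time.time(),
    )

    design = replace(config.design, seed=seeds["simulate"])
    dataset = generate_study(design, noise=config.noise)
    manifest.n_samples = len(dataset)

    mask = build_scatter_mask(dataset.grid, config.preprocess)
    clean = EEMDataset([preprocess_sample(s, mask, config.preprocess) for s in dataset])

    cal_idx, pred_idx = stratified_split_indices(
        clean.labels, replace(config.split, seed=seeds["split"])
    )
    manifest.n_calibration = len(cal_idx)
    manifest.n_prediction = len(pred_idx)

    tensor = EEMTensor.from_dataset(clean, mask)
    diagnostics = select_components(
        tensor,
        F_range=config.parafac_F_range,
        tol=config.parafac_tol,
        max_iter=config.parafac_max_iter,
        seed=seeds["parafac"],
    )
    model = fit_parafac(
        tensor,
        diagnostics.selected_F,
        tol=config.parafac_tol,
        max_iter=config.parafac_max_iter,
        seed=seeds["parafac"],
    )
    manifest.parafac_diagnostics = diagnostics.to_frame()
    manifest.parafac_selected_F = diagnostics.selected_F
    manifest.score_table = component_scores_vs_level(model, tensor.labels)

    manifest.pls_reports = run_plsr_family(
        clean, cal_idx, pred_idx,
        excitations=config.excitations,
        preprocessings=config.pls_preprocessings,
        augmentation=config.augmentation,
        metrics=config.metrics,
        seed=seeds["pls"],
    )
    manifest.cnn1d_reports = run_cnn1d_family(
        clean, cal_idx, pred_idx,
        excitations=config.excitations,
        augmentation=config.augmentation,
        metrics=config.metrics,
        train_config=TrainConfig.for_1d(epochs_max=config.epochs_1d),
        seed=seeds["cnn1d"],
    )
    manifest.cnn2d_reports = run_cnn2d_family(
        clean, cal_idx, pred_idx,
        image_augment=config.image_augment,
        metrics=config.metrics,
        train_config=TrainConfig.for_2d(epochs_max=config.epochs_2d),
        seed=seeds["cnn2d"],
    )

    manifest.finished_at = time.time()
    if output_dir is not None:
        manifest.save(output_dir)
    return manifest


def compare_models(reports: list[RegressionReport] | RunManifest) -> pd.DataFrame:
    """Rank models by prediction RMSE ascending, ties broken by RPD
    descending; the result is a permutation of the input set."""
    if isinstance(reports, RunManifest):
        reports = reports.all_reports
    rows = [
        {"model": r.descriptor, "RMSEP": r.RMSEP, "RPD": r.RPD, "R2P": r.R2P, "LOD": r.LOD}
        for r in reports
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(["RMSEP", "RPD"], ascending=[True, False], kind="mergesort")
    return df.reset_index(drop=True)
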