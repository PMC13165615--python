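"""Non-negative PARAFAC (trilinear) decomposition of EEM stacks.

A concentration series of EEMs forms a three-way array X (sample i x
emission j x excitation k) that, for dilute mixtures obeying Beer-Lambert
behavior, is approximately trilinear:

    x_ijk = sum_f a_if * b_jf * c_kf + e_ijk

with sample scores a (relative concentrations), emission loadings b and
excitation loadings c, all physically non-negative.  Fitting uses
hierarchical alternating least squares (HALS) with an SVD-based
initialization; model order is selected jointly from explained variance and
the core consistency diagnostic (corcondia), which collapses when the model
is overfactored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ScatterMask, zero_fill_scatter
from .synthetic import EEMDataset

__all__ = [
    "EEMTensor",
    "ParafacModel",
    "ParafacDiagnostics",
    "fit_parafac",
    "explained_variance",
    "core_consistency",
    "select_components",
    "component_scores_vs_level",
]


@dataclass
class EEMTensor:
    """Three-way array (sample x emission x excitation) plus sample labels."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tensor must be three-way")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("one label per sample required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor must be finite")
        if self.values.min() < 0:
            raise ValueError("tensor must be non-negative (zero-fill scatter first)")

    @classmethod
    def from_dataset(cls, dataset: EEMDataset, mask: ScatterMask | None = None) -> "EEMTensor":
        """Stack a dataset into a tensor, optionally zero-filling scatter
        pixels (the decomposition input path)."""
        samples = dataset.samples
        if mask is not None:
            samples = [zero_fill_scatter(s, mask) for s in samples]
        # intensity matrices are excitation x emission; tensor wants
        # emission as mode 1 and excitation as mode 2
        values = np.stack([s.intensity.T for s in samples])
        return cls(values=values, labels=dataset.labels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ParafacModel:
    """Fitted factors: scores (sample x F) and unit-norm emission/excitation
    loadings, with component magnitude absorbed into the scores."""

    F: int
    scores: np.ndarray
    emission_loadings: np.ndarray
    excitation_loadings: np.ndarray
    n_iterations: int
    converged: bool
    fit_residual_ss: float
    residual_history: list[float] = field(default_factory=list)

    @property
    def factors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.scores, self.emission_loadings, self.excitation_loadings

    def reconstruct(self) -> np.ndarray:
        return np.einsum("if,jf,kf->ijk", *self.factors)

    def sorted_by_emission_peak(self) -> "ParafacModel":
        """Permute components by ascending emission-peak index, the fixed
        reporting convention that makes runs comparable."""
        order = np.argsort(np.argmax(self.emission_loadings, axis=0))
        return ParafacModel(
            F=self.F,
            scores=self.scores[:, order],
            emission_loadings=self.emission_loadings[:, order],
            excitation_loadings=self.excitation_loadings[:, order],
            n_iterations=self.n_iterations,
            converged=self.converged,
            fit_residual_ss=self.fit_residual_ss,
            residual_history=self.residual_history,
        )


@dataclass
class ParafacDiagnostics:
    """Per-model-order fit diagnostics and the selected order."""

    F_values: list[int]
    explained_variance_pct: list[float]
    core_consistency_pct: list[float]
    selected_F: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_components": self.F_values,
                "explained_variance_pct": self.explained_variance_pct,
                "core_consistency_pct": self.core_consistency_pct,
            }
        )


def _khatri_rao(B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product, row order matching a C-order reshape."""
    return (B[:, None, :] * C[None, :, :]).reshape(B.shape[0] * C.shape[0], -1)


def _svd_init(X: np.ndarray, F: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Leading left singular vectors of each unfolding, sign-flipped to a
    positive majority, clipped at zero and offset by a small epsilon so no
    column starts locked at zero."""
    factors = []
    for mode in range(3):
        unf = np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)
        U, _, _ = np.linalg.svd(unf, full_matrices=False)
        k = min(F, U.shape[1])
        V = U[:, :k]
        signs = np.where(V.sum(axis=0) >= 0, 1.0, -1.0)
        V = V * signs
        if k < F:  # pad with small random columns if the unfolding is thin
            extra = rng.random((V.shape[0], F - k)) * 0.1
            V = np.hstack([V, extra])
        factors.append(np.clip(V, 0.0, None) + 1e-9)
    return factors


def fit_parafac(
    tensor: EEMTensor | np.ndarray,
    F: int,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int = 0,
    init: str = "svd",
    n_restarts: int = 0,
) -> ParafacModel:
    """Fit a non-negative F-component PARAFAC model by HALS.

    Iterations stop when the relative reconstruction error changes by less
    than ``tol`` between sweeps or ``max_iter`` sweeps are reached.  The
    returned loadings are unit-norm with magnitudes absorbed into the
    scores.

    The default is a single deterministic run from the SVD init.
    ``n_restarts`` adds that many random-init runs and returns the fit with
    the smallest residual -- useful for overfactored models, whose loss
    surface has many local minima (e.g. when probing the core-consistency
    collapse).
    """
    if n_restarts > 0:
        fits = [
            fit_parafac(tensor, F, tol=tol, max_iter=max_iter, seed=seed, init=init)
        ]
        for r in range(n_restarts):
            fits.append(
                fit_parafac(tensor, F, tol=tol, max_iter=max_iter,
                            seed=seed + 1 + r, init="random")
            )
        return min(fits, key=lambda m: m.fit_residual_ss)
    X = tensor.values if isinstance(tensor, EEMTensor) else np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise ValueError("tensor must be three-way")
    if F < 1:
        raise ValueError("F must be >= 1")
    if F > min(X.shape):
        raise ValueError(f"F={F} exceeds the smallest tensor dimension {min(X.shape)}")
    norm_x_sq = float(np.sum(X * X))
    if norm_x_sq == 0.0:
        raise ValueError("all-zero tensor cannot be decomposed")

    rng = np.random.default_rng(seed)
    if init == "svd":
        factors = _svd_init(X, F, rng)
    elif init == "random":
        factors = [rng.random((dim, F)) + 1e-9 for dim in X.shape]
    else:
        raise ValueError(f"unknown init '{init}'")

    unfoldings = [np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1) for mode in range(3)]

    prev_err = np.inf
    history: list[float] = []
    converged = False
    n_iter = 0
    res_sq = norm_x_sq
    for n_iter in range(1, max_iter + 1):
        for mode in range(3):
            others = [factors[m] for m in range(3) if m != mode]
            kr = _khatri_rao(*others)
            M = unfoldings[mode] @ kr  # MTTKRP
            W = (others[0].T @ others[0]) * (others[1].T @ others[1])
            A = factors[mode]
            for f in range(F):
                denom = W[f, f]
                if denom < 1e-30:
                    denom = 1e-30
                col = A[:, f] + (M[:, f] - A @ W[:, f]) / denom
                A[:, f] = np.clip(col, 0.0, None)
            factors[mode] = A
            if mode == 2:
                # residual via grams, reusing this mode's MTTKRP
                gram = (factors[0].T @ factors[0]) * (factors[1].T @ factors[1]) * (
                    factors[2].T @ factors[2]
                )
                res_sq = norm_x_sq - 2.0 * float(np.sum(factors[2] * M)) + float(np.sum(gram))
        rec_err = np.sqrt(max(res_sq, 0.0) / norm_x_sq)
        history.append(rec_err)
        if abs(prev_err - rec_err) < tol:
            converged = True
            break
        prev_err = rec_err

    A, B, C = factors
    # absorb loading magnitudes into the scores (unit-norm convention)
    for mat in (B, C):
        norms = np.linalg.norm(mat, axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        mat /= norms
        A *= norms

    return ParafacModel(
        F=F,
        scores=A,
        emission_loadings=B,
        excitation_loadings=C,
        n_iterations=n_iter,
        converged=converged,
        fit_residual_ss=float(max(res_sq, 0.0)),
        residual_history=history,
    ).sorted_by_emission_peak()


def explained_variance(model: ParafacModel, tensor: EEMTensor | np.ndarray) -> float:
    """Percent of the tensor's sum of squares captured by the model:
    100 * (1 - ||X - Xhat||^2 / ||X||^2)."""
    X = tensor.values if isinstance(tensor, EEMTensor) else np.asarray(tensor, dtype=float)
    if X.shape != (model.scores.shape[0], model.emission_loadings.shape[0],
                   model.excitation_loadings.shape[0]):
        raise ValueError("model and tensor shapes disagree")
    sstot = float(np.sum(X * X))
    if sstot == 0.0:
        raise ValueError("zero tensor norm")
    ssres = float(np.sum((X - model.reconstruct()) ** 2))
    return 100.0 * (1.0 - ssres / sstot)


def core_consistency(model: ParafacModel, tensor: EEMTensor | np.ndarray) -> float:
    """Core consistency diagnostic (corcondia, Bro & Kiers form).

    With the model's factor matrices fixed, the least-squares Tucker3 core
    G (F x F x F) is compared against the superidentity T:
    100 * (1 - sum (g - t)^2 / F).  Values near 100 support trilinearity;
    overfactored models collapse (possibly to negative values, which are
    reported as-is).
    """
    X = tensor.values if isinstance(tensor, EEMTensor) else np.asarray(tensor, dtype=float)
    factors = model.factors
    F = model.F
    for mat in factors:
        if np.linalg.matrix_rank(mat) < F:
            raise ValueError(
                "degenerate factor matrix (rank-deficient); the core is not identifiable"
            )
    # least-squares core: G = X x_0 pinv(A) x_1 pinv(B) x_2 pinv(C)
    G = X
    for mode, mat in enumerate(factors):
        G = np.moveaxis(np.tensordot(np.linalg.pinv(mat), G, axes=(1, mode)), 0, mode)
    T = np.zeros((F, F, F))
    for f in range(F):
        T[f, f, f] = 1.0
    return 100.0 * (1.0 - float(np.sum((G - T) ** 2)) / F)


def select_components(
    tensor: EEMTensor | np.ndarray,
    F_range=range(1, 6),
    corcondia_threshold: float = 60.0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int = 0,
) -> ParafacDiagnostics:
    """Fit every model order in ``F_range`` and select the largest F whose
    core consistency stays at or above the threshold (fallback F = 1)."""
    F_values = list(F_range)
    if not F_values:
        raise ValueError("F_range must be non-empty")
    ev, cc = [], []
    for F in F_values:
        model = fit_parafac(tensor, F, tol=tol, max_iter=max_iter, seed=seed)
        ev.append(explained_variance(model, tensor))
        try:
            cc.append(core_consistency(model, tensor))
        except ValueError:
            cc.append(float("nan"))  # degenerate fit: treat as failed diagnostic
    passing = [F for F, c in zip(F_values, cc) if np.isfinite(c) and c >= corcondia_threshold]
    if passing:
        selected = max(passing)
    else:
        warnings.warn(
            "no model order reached the core-consistency threshold; falling back to F=1",
            stacklevel=2,
        )
        selected = 1
    return ParafacDiagnostics(
        F_values=F_values,
        explained_variance_pct=ev,
        core_consistency_pct=cc,
        selected_F=selected,
    )


def component_scores_vs_level(model: ParafacModel, labels) -> pd.DataFrame:
    """Mean component score per adulteration level, ordered by level."""
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != model.scores.shape[0]:
        raise ValueError("labels do not align with the sample mode")
    df = pd.DataFrame(
        model.scores, columns=[f"component_{f + 1}" for f in range(model.F)]
    )
    df["level"] = labels
    out = df.groupby("level", as_index=False).mean().sort_values("level")
    return out.reset_index(drop=True)
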