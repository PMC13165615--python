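# Methods

`eemkit` implements a complete chemometric workflow for quantifying
coconut-milk adulteration of bovine milk from excitation–emission matrix
(EEM) fluorescence: simulation of a concentration-series study, scatter
removal, non-negative trilinear (PARAFAC) decomposition with model-order
diagnostics, and three regression families (PLSR on emission slices, a 1-D
CNN on the same slices, a 2-D CNN on rendered EEM images) evaluated with
R², RMSE, RPD and a multivariate limit of detection.

## The measurement model behind the simulator

Bovine milk fluoresces mainly through two intrinsic chromophores: the
tryptophan residues of milk proteins (excitation ≈ 290 nm, emission ≈
350 nm) and riboflavin (excitation maxima ≈ 380 and 460 nm, emission ≈
525 nm). Coconut milk lacks both, so blending it into bovine milk dilutes
these signals in proportion to the added volume fraction *p* (% v/v). The
simulator (`eemkit.synthetic`) encodes exactly this mechanism:

```
X(p) = g · [ (1 − p/100) · B + (p/100) · C ] + S + ε
```

* `B`, `C` — pure bovine and coconut surfaces, each a sum of separable
  Gaussian fluorophores (`FluorophoreSpec`). Riboflavin is modeled as one
  fluorophore with two excitation centers sharing one emission profile, so
  it is a single trilinear component. The coconut surface is a broad,
  featureless hump at 5 % of the total bovine amplitude — plant emulsions
  fluoresce weakly across the whole landscape.
* `g` — per-scan detector gain, uniform on (0.97, 1.03).
* `S` — first- and second-order Rayleigh ridges, Gaussian in emission
  around `em = ex` and `em = 2·ex` (σ = 8 nm), each peaking at 50 % of the
  bovine maximum so that scatter locally dominates the chemistry and its
  removal is a meaningful test.
* `ε` — i.i.d. Gaussian detector noise, σ = 1 % of the bovine peak.
  Intensities are clipped at zero afterwards.

Two further disturbance terms make the replicate structure realistic
rather than idealized:

* **Per-replicate concentration variability** (`concentration_cv`,
  default 2 %): every replicate is prepared individually, so each
  fluorophore's effective amplitude varies independently between scans.
  This term is not cosmetic — without it the two bovine components'
  concentration profiles are *exactly* proportional (both scale as
  1 − p/100), the sample-mode factor matrix has rank 1, and the trilinear
  model is unidentifiable (the Kruskal condition k_A + k_B + k_C ≥ 2F + 2
  fails). The core-consistency diagnostic is meaningless on such data.
* **Per-scan emission peak jitter** (`emission_shift_sigma_nm`, default
  1 nm): monochromator reproducibility and matrix effects shift emission
  bands slightly between scans. This supplies the mild departure from
  exact trilinearity that every real EEM series carries. On data that are
  exactly trilinear up to i.i.d. noise, an overfactored PARAFAC model can
  absorb noise without disturbing the core (we measure core consistency
  ≈ +99 for F = 3 on rank-2 data without jitter), so the diagnostic's
  characteristic overfactoring collapse cannot occur at all; with ~1 nm
  jitter it collapses exactly as it should.

The default study design is 9 levels (0, 2.5, 5, 10, 20, 30, 40, 50,
100 % v/v) × 10 replicates = 90 scans on the instrument grid (excitation
250–500 nm in 5 nm steps; emission 280–600 nm, step configurable, default
5 nm → 51 × 65 matrices). `NoiseSpec.noiseless()` switches every
disturbance off, which is the configuration used for exact-recovery
oracles.

What the simulator does **not** emulate: inner-filter effects, quenching,
Raman scatter as a separate feature, vitamin A as a resolved component,
and brand-to-brand compositional variation. Passing tests therefore
demonstrate correctness of the algorithms under the linear-mixing model,
not robustness to every photophysical artifact of real emulsions.

## Scatter removal (`eemkit.preprocess`)

First-order scatter is masked within ±25 nm of the excitation wavelength,
second-order within ±20 nm of twice the excitation wavelength. Masked
pixels are reconstructed by 2-D cubic interpolation over the unmasked
grid; outside the convex hull of source points (matrix corners) the
interpolant is undefined and nearest-neighbor extrapolation guarantees a
finite result. The surface is then smoothed with a Gaussian filter of
σ = 1.5 *grid units* (the common image-filter reading; configurable) with
reflective boundaries — this preserves constants and avoids edge
darkening — and negative values are clipped to zero, in that order.

Two input paths leave this module: the regression families consume the
interpolated surfaces, while the PARAFAC path re-zeroes the masked region
(`zero_fill_scatter`) — zeros are numerically stable for the
decomposition, and no missing-data weighting is applied. An optional
water-Raman band is available but off by default; the ±25 nm first-order
band already covers the Raman ridge at this resolution.

`normalize_global` rescales a dataset by a single maximum onto [0, 255]
(8-bit image range). The normalization constant can be supplied
explicitly; the pipeline always passes the *calibration-set* maximum so
that no statistic of the prediction data leaks into preprocessing.

## Non-negative PARAFAC (`eemkit.parafac`)

The cleaned scans are stacked into a three-way array X (sample × emission
× excitation) and decomposed as

```
x_ijk = Σ_f a_if · b_jf · c_kf + e_ijk ,   a, b, c ≥ 0
```

Fitting is hierarchical alternating least squares (HALS): each factor
column in turn gets an exact non-negative coordinate update, which makes
the objective monotonically non-increasing. Initialization takes the
leading left singular vectors of each unfolding, sign-flipped to a
positive majority, clipped at zero and offset by 1e-9 so no column starts
locked at zero. Convergence is declared when the relative reconstruction
error changes by less than 1e-6 between sweeps (cap 2000). The default is
a single deterministic SVD-init run; `n_restarts` adds random-init
restarts and keeps the best fit, which matters for deliberately
overfactored models whose loss surface has many local minima. Returned
loadings are unit-norm with magnitudes absorbed into the scores, and
components are reported in ascending emission-peak order so runs are
comparable despite permutation indeterminacy.

Model order is chosen jointly from explained variance,
`100·(1 − ‖X − X̂‖²/‖X‖²)`, and the core consistency diagnostic
(Bro–Kiers): with the factor matrices fixed, the least-squares Tucker3
core G is computed via mode-wise pseudo-inverses and compared with the
superidentity T, `100·(1 − Σ(g − t)²/F)`. Values near 100 support
trilinearity; overfactored models collapse, possibly to negative values,
which are reported as-is (flooring at zero is a display convention only).
A one-component model always scores exactly 100 — at any ALS stationary
point the 1×1×1 least-squares core equals 1 — so the diagnostic is only
informative for F ≥ 2. Exactly rank-deficient factor matrices (e.g. a
dead component) raise an error rather than returning a silently
meaningless number. `select_components` picks the largest F whose core
consistency stays at or above 60 % (fallback F = 1 with a warning).

On the full default simulation the diagnostic selects **three**
components — correctly, because the weak coconut hump is a genuine third
trilinear component of the generator. The two-component structure of a
bovine-only series is reproduced on the configuration with the coconut
amplitude set to zero, where F = 2 explains > 99.99 % of a noiseless
stack and F = 3 on noisy data collapses the core.

## PLSR on emission slices (`eemkit.regression`)

Emission spectra are extracted at 290 nm (tryptophan), 330 nm (vitamin
A/retinol region) and 450 nm (riboflavin). Three preprocessing variants
are compared: raw, multiplicative scatter correction (MSC: each spectrum
is regressed on the calibration-mean reference, x ≈ a + b·ref, and
corrected to (x − a)/b), and a Savitzky–Golay first derivative (window
11, order 2, per-grid-step units; both unstated upstream and exposed as
config). The MSC reference is learned on calibration spectra only and
frozen for prediction data.

Calibration spectra are expanded ×10 in count (“×9 augmentation”: 9
perturbed copies plus the original, 63 → 630) with
`x' = m·x + b·1 + s·λ̃`, m ~ U(0.9, 1.1), offset b and slope s uniform
within ±10 % of the spectrum's standard deviation, λ̃ the wavelength axis
rescaled to [−1, 1]. These magnitudes are package defaults chosen as mild
instrument-drift surrogates, and augmentation is applied after MSC/SG1 so
perturbations act on the modeling representation (switchable). The
prediction set is never augmented.

PLSR itself is scikit-learn's NIPALS implementation without internal
scaling; the latent dimension, when not fixed, minimizes 10-fold
cross-validated RMSE on the calibration set (cap 15) with a
one-standard-error tie-break toward fewer components. The internal
validation stream reported as R²V/RMSEV consists of the out-of-fold
predictions at the chosen dimension.

A note on augmentation and simulated data: on real spectra augmentation
regularizes against instrument drift the model will actually encounter;
on the simulator's clean linear mixtures it mainly injects perturbations
the test data do not contain, so the augmented PLSR is *worse* than the
non-augmented one (RMSEP ≈ 5 vs ≈ 2 % v/v at 450 nm). The package
reports both, and the model-family comparisons below always reference the
augmented variant against the augmented image model, like for like.

## CNN regression (`eemkit.cnn`, engine in `eemkit.nn`)

No deep-learning framework is part of this package's dependency set; the
two small networks run on a purpose-built NumPy engine (float32, im2col /
shifted-matmul convolutions, analytic gradients verified against finite
differences in the test suite). Both architectures share one lightweight
block:

```
conv(16 filters, He-normal) → ReLU → max-pool → flatten
→ dense(64, ReLU) → dropout(0.2) → dense(1, linear)
```

* **1-D:** kernel 3, pool 2, on z-score-standardized emission slices
  (per-wavelength statistics fit on the training stream only, sd floored
  at 1e-12; inputs get a trailing channel axis). With the 65-point
  default emission axis the flattened width is 496, so the dense layer
  holds 496·64 + 64 = 31 808 parameters.
* **2-D:** kernel 3×3, pool 2×2, on 224×224×3 images; valid padding
  throughout (padding is a documented choice — flatten size 111·111·16 =
  197 136 depends on it).

Training uses Adam (lr 1e-3 for 1-D, 5e-4 for 2-D), MSE loss with MAE
monitored, batch 16, up to 300 epochs with early stopping (patience 20,
best weights restored) and reduce-on-plateau scheduling (factor 0.5,
patience 10, floor 1e-6). The early-stopping validation stream holds out
20 % of the original calibration samples, stratified by level and used
un-augmented — the training stream is the augmented one, which is why
training loss can sit above validation loss.

EEM images are produced by a deterministic raster filled-contour
renderer: the globally normalized matrix is bilinearly upsampled to
512×512, quantized into 16 fixed intensity bands over [0, 255] (the
filled contour), colored with a fixed perceptually-uniform colormap LUT
(viridis; configurable, fixed limits), resized bilinearly to 224×224 RGB
and scaled to [0, 1]. Identical matrices yield bit-identical images.
Image augmentation acts on the normalized *matrices* before rendering:
9 copies per original with amplitude scale U(0.85, 1.15) plus pixelwise
Gaussian noise, σ ~ U(1, 5) in 0–255 units, clipped at zero, then
re-rendered; 63 calibration matrices become 630 training images while the
27 prediction images stay untouched.

## Evaluation (`eemkit.evaluation`)

The 70:30 calibration/prediction split is stratified by level
(round(0.7·n) per level, seeded; a level needs ≥ 2 replicates), and every
model family sees the identical partition. Metrics:

* `R² = 1 − Σ(y_p − y_a)² / Σ(y_a − ȳ)²` (total sum of squares about the
  *reference* values; a variant placing predicted values in the
  denominator exists behind a flag for comparison, as that form
  occasionally appears in print).
* `RMSE = √(Σ(y_p − y_a)²/n)` per stream (calibration / validation /
  prediction).
* `RPD = sd(y_reference, n−1) / RMSEP`; > 3 is the usual
  practically-useful threshold.
* `LOD = 3.3 × RMSE`, the ICH-style 3.3·σ multivariate convention; the
  factor is configurable (set 3.0 for the literal 3σ form). The RMSE
  stream is the validation one when it exists, otherwise the prediction
  RMSE. Table display uses half-up decimal rounding to two places
  (`round_half_up`), because float banker's rounding would turn 11.055
  into 11.05.

## Orchestration and reproducibility

`run_experiment` executes simulate → preprocess → PARAFAC →
PLSR (3 excitations × 3 preprocessings × 2 augmentation states) → 1-D CNN
(3 excitations) → 2-D CNN (±augmentation) on one shared split and writes
CSV/JSON tables plus a manifest. A master seed fans out to per-stage
seeds by stable hashing, so adding a stage never shifts earlier random
streams; every stochastic element (simulation, splits, augmentation,
weight init, batch shuffling, dropout) descends from it. Non-CNN stages
are bit-reproducible; CNN runs are reproducible on a single-threaded
deterministic BLAS configuration.

## Problem sizes used by the test suite

Full-schedule CNN training (300 epochs) is a production setting; the
package's own test and acceptance runs use desk-scale budgets chosen as
package defaults for CI-style verification: the model-family comparison
trains both 2-D CNN variants for 6 epochs on the 630-image augmented and
63-image non-augmented streams over three seeds with majority voting, and
the toy pipeline integration test uses a 12-sample study. At these
budgets the augmented 2-D CNN reaches RMSEP ≈ 2.4 % v/v on the default
simulation, below the best augmented PLSR slice model (≈ 5 % v/v),
reproducing the qualitative ranking that motivates image-based
regression. The multi-restart brute-force PARAFAC oracle runs on 3×3×3
tensors.

## Known limitations

* The CNN engine is minimal by design: no padding options, strides,
  batch-norm or GPU path; it exists to make the two reference
  architectures runnable and testable without a framework dependency.
* Corcondia on near-degenerate fits is numerically explosive by nature;
  the package raises on exactly rank-deficient factors instead of
  returning arbitrary large negatives, and reports negatives otherwise.
* The simulator's linear-mixing assumption ignores inner-filter and
  quenching effects, so absolute metric values on synthetic data are
  optimistic relative to real emulsions; the package's claims are about
  algorithmic correctness and relative model ordering.
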