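"""Synthetic excitation-emission matrix (EEM) generator.

Emulates fluorescence landscapes of bovine milk progressively adulterated
with coconut milk.  Bovine milk carries two dominant intrinsic fluorophores
(a tryptophan-like protein band, ex/em ~ 290/350 nm, and a riboflavin-like
band with excitation maxima near 380 and 460 nm emitting around 525 nm);
coconut milk contributes only a weak, featureless background.  Mixture
spectra are linear in the volume fraction, corrupted by first- and
second-order Rayleigh scatter ridges, multiplicative gain fluctuation and
additive detector noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EEMGrid",
    "FluorophoreSpec",
    "StudyDesign",
    "NoiseSpec",
    "EEMSample",
    "EEMDataset",
    "default_bovine_specs",
    "default_coconut_specs",
    "make_pure_profile",
    "add_scatter",
    "simulate_sample",
    "generate_study",
]

#: Peak intensity (arbitrary units) of the pure-bovine surface; noise and
#: scatter defaults below are expressed relative to this value.
BOVINE_PEAK = 1000.0


@dataclass(frozen=True)
class EEMGrid:
    """Wavelength grid of an EEM scan (nm)."""

    excitation_nm: np.ndarray
    emission_nm: np.ndarray

    def __post_init__(self):
        ex = np.asarray(self.excitation_nm, dtype=float)
        em = np.asarray(self.emission_nm, dtype=float)
        if ex.ndim != 1 or em.ndim != 1 or ex.size < 2 or em.size < 2:
            raise ValueError("grid axes must be 1-D with at least two points")
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise ValueError("grid wavelengths must be strictly increasing")
        object.__setattr__(self, "excitation_nm", ex)
        object.__setattr__(self, "emission_nm", em)

    @classmethod
    def default(cls, emission_step: float = 5.0) -> "EEMGrid":
        """Instrument grid: excitation 250-500 nm in 5 nm steps, emission
        280-600 nm (step configurable, default 5 nm)."""
        return cls(
            excitation_nm=np.arange(250.0, 500.0 + 1e-9, 5.0),
            emission_nm=np.arange(280.0, 600.0 + 1e-9, emission_step),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.excitation_nm.size, self.emission_nm.size


@dataclass(frozen=True)
class FluorophoreSpec:
    """Sum-of-Gaussians surrogate for one fluorophore.

    A fluorophore may have several excitation maxima (riboflavin shows two)
    but shares a single emission profile, so each spec contributes exactly
    one trilinear (rank-1 in ex x em) component.
    """

    name: str
    ex_centers_nm: tuple[float, ...]
    ex_widths_nm: tuple[float, ...]
    em_center_nm: float
    em_width_nm: float
    amplitude: float
    source: str = "bovine"

    def __post_init__(self):
        if len(self.ex_centers_nm) != len(self.ex_widths_nm):
            raise ValueError("one width per excitation center required")
        if any(w <= 0 for w in self.ex_widths_nm) or self.em_width_nm <= 0:
            raise ValueError("widths must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.source not in ("bovine", "coconut"):
            raise ValueError("source must be 'bovine' or 'coconut'")


def default_bovine_specs() -> list[FluorophoreSpec]:
    """Tryptophan-like and riboflavin-like bovine fluorophores."""
    return [
        FluorophoreSpec(
            name="tryptophan",
            ex_centers_nm=(290.0,),
            ex_widths_nm=(15.0,),
            em_center_nm=350.0,
            em_width_nm=25.0,
            amplitude=BOVINE_PEAK,
            source="bovine",
        ),
        FluorophoreSpec(
            name="riboflavin",
            ex_centers_nm=(380.0, 460.0),
            ex_widths_nm=(22.0, 22.0),
            em_center_nm=525.0,
            em_width_nm=30.0,
            amplitude=0.6 * BOVINE_PEAK,
            source="bovine",
        ),
    ]


def default_coconut_specs() -> list[FluorophoreSpec]:
    """Weak, broad coconut background (~5% of the bovine total amplitude)."""
    total = sum(s.amplitude for s in default_bovine_specs())
    return [
        FluorophoreSpec(
            name="coconut_background",
            ex_centers_nm=(340.0,),
            ex_widths_nm=(80.0,),
            em_center_nm=430.0,
            em_width_nm=90.0,
            amplitude=0.05 * total,
            source="coconut",
        )
    ]


@dataclass(frozen=True)
class StudyDesign:
    """Concentration levels (% v/v coconut milk) and replication."""

    levels_pct: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0)
    replicates_per_level: int = 10
    seed: int = 0

    def __post_init__(self):
        if any(not 0.0 <= v <= 100.0 for v in self.levels_pct):
            raise ValueError("levels must lie within [0, 100] % v/v")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.levels_pct) * self.replicates_per_level


@dataclass(frozen=True)
class NoiseSpec:
    """Instrumental disturbance model.

    additive_sigma     -- detector noise s.d. (intensity units)
    gain_range         -- per-scan multiplicative gain interval (low, high)
    scatter_amplitude_1st/2nd -- Rayleigh ridge peak heights
    scatter_sigma_nm   -- Gaussian ridge width
    concentration_cv   -- per-replicate relative s.d. of each fluorophore's
                          amplitude (replicates are prepared individually)
    emission_shift_sigma_nm -- per-scan emission peak-position jitter
                          (monochromator reproducibility / matrix effects);
                          the mild departure from exact trilinearity that
                          real spectra always carry
    """

    additive_sigma: float = 0.01 * BOVINE_PEAK
    gain_range: tuple[float, float] = (0.97, 1.03)
    scatter_amplitude_1st: float = 0.5 * BOVINE_PEAK
    scatter_amplitude_2nd: float = 0.5 * BOVINE_PEAK
    scatter_sigma_nm: float = 8.0
    concentration_cv: float = 0.02
    emission_shift_sigma_nm: float = 1.0

    def __post_init__(self):
        if self.additive_sigma < 0:
            raise ValueError("additive_sigma must be >= 0")
        if self.concentration_cv < 0:
            raise ValueError("concentration_cv must be >= 0")
        low, high = self.gain_range
        if not (0 < low <= 1 <= high):
            raise ValueError("gain_range must satisfy 0 < low <= 1 <= high")
        if self.scatter_amplitude_1st < 0 or self.scatter_amplitude_2nd < 0:
            raise ValueError("scatter amplitudes must be >= 0")
        if self.scatter_sigma_nm <= 0:
            raise ValueError("scatter_sigma_nm must be positive")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        return cls(additive_sigma=0.0, gain_range=(1.0, 1.0),
                   scatter_amplitude_1st=0.0, scatter_amplitude_2nd=0.0,
                   concentration_cv=0.0, emission_shift_sigma_nm=0.0)


@dataclass
class EEMSample:
    """One EEM scan: intensity matrix (excitation x emission) plus label."""

    grid: EEMGrid
    intensity: np.ndarray
    adulteration_pct: float
    replicate_id: int = 0
    sample_id: str = ""

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid {self.grid.shape}"
            )
        if not 0.0 <= self.adulteration_pct <= 100.0:
            raise ValueError("adulteration_pct must lie in [0, 100]")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if not self.sample_id:
            self.sample_id = f"pct{self.adulteration_pct:g}_rep{self.replicate_id}"

    def with_intensity(self, intensity: np.ndarray) -> "EEMSample":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class EEMDataset:
    """Ordered collection of samples on a shared grid."""

    samples: list[EEMSample]
    global_max: float = field(init=False)

    def __post_init__(self):
        if not self.samples:
            raise ValueError("dataset must contain at least one sample")
        g0 = self.samples[0].grid
        for s in self.samples[1:]:
            if s.grid.shape != g0.shape or not (
                np.array_equal(s.grid.excitation_nm, g0.excitation_nm)
                and np.array_equal(s.grid.emission_nm, g0.emission_nm)
            ):
                raise ValueError("all samples must share one grid")
        self.global_max = float(max(s.intensity.max() for s in self.samples))

    @property
    def grid(self) -> EEMGrid:
        return self.samples[0].grid

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.adulteration_pct for s in self.samples])

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def subset(self, indices) -> "EEMDataset":
        return EEMDataset([self.samples[i] for i in indices])

    def map_intensity(self, fn) -> "EEMDataset":
        return EEMDataset([s.with_intensity(fn(s.intensity)) for s in self.samples])


def make_pure_profile(specs: list[FluorophoreSpec], grid: EEMGrid) -> np.ndarray:
    """Noise-free EEM surface of a fluorophore mixture.

    Each spec contributes amplitude * (sum of excitation Gaussians) x
    (emission Gaussian), i.e. a rank-1 excitation-emission surface.
    """
    if not specs:
        raise ValueError("no fluorophores")
    ex = grid.excitation_nm[:, None]
    em = grid.emission_nm[None, :]
    out = np.zeros(grid.shape)
    for spec in specs:
        ex_prof = np.zeros_like(ex)
        for c, w in zip(spec.ex_centers_nm, spec.ex_widths_nm):
            ex_prof = ex_prof + np.exp(-((ex - c) ** 2) / (2.0 * w**2))
        em_prof = np.exp(-((em - spec.em_center_nm) ** 2) / (2.0 * spec.em_width_nm**2))
        out += spec.amplitude * ex_prof * em_prof
    return out


def add_scatter(intensity: np.ndarray, grid: EEMGrid, noise: NoiseSpec) -> np.ndarray:
    """Superimpose first- (em = ex) and second-order (em = 2*ex) Rayleigh
    ridges.  Ridges are Gaussian in the emission direction; centers outside
    the emission range still contribute their tails."""
    ex = grid.excitation_nm[:, None]
    em = grid.emission_nm[None, :]
    s2 = 2.0 * noise.scatter_sigma_nm**2
    ridge1 = noise.scatter_amplitude_1st * np.exp(-((em - ex) ** 2) / s2)
    ridge2 = noise.scatter_amplitude_2nd * np.exp(-((em - 2.0 * ex) ** 2) / s2)
    return intensity + ridge1 + ridge2


def simulate_sample(
    adulteration_pct: float,
    bovine_profile: np.ndarray,
    coconut_profile: np.ndarray,
    noise: NoiseSpec,
    seed: int,
    grid: EEMGrid | None = None,
    replicate_id: int = 0,
) -> EEMSample:
    """Simulate one adulterated-milk scan.

    intensity = gain * [(1 - p/100) * bovine + (p/100) * coconut]
                + scatter ridges + additive Gaussian noise, clipped at 0.
    """
    bovine_profile = np.asarray(bovine_profile, dtype=float)
    coconut_profile = np.asarray(coconut_profile, dtype=float)
    if bovine_profile.shape != coconut_profile.shape:
        raise ValueError("bovine and coconut profiles must share one shape")
    if not 0.0 <= adulteration_pct <= 100.0:
        raise ValueError("adulteration_pct must lie in [0, 100]")
    if grid is None:
        grid = EEMGrid.default()
    if bovine_profile.shape != grid.shape:
        raise ValueError("profile shape does not match grid")

    rng = np.random.default_rng(seed)
    frac = adulteration_pct / 100.0
    gain = rng.uniform(*noise.gain_range)
    mix = gain * ((1.0 - frac) * bovine_profile + frac * coconut_profile)
    if noise.emission_shift_sigma_nm > 0:
        # per-scan emission-axis jitter of the fluorescence signal only
        # (scatter ridges sit at the true instrument wavelengths)
        delta = rng.normal(0.0, noise.emission_shift_sigma_nm)
        em = grid.emission_nm
        mix = np.stack([np.interp(em, em + delta, row) for row in mix])
    mix = add_scatter(mix, grid, noise)
    if noise.additive_sigma > 0:
        mix = mix + rng.normal(0.0, noise.additive_sigma, size=mix.shape)
    mix = np.clip(mix, 0.0, None)
    return EEMSample(
        grid=grid,
        intensity=mix,
        adulteration_pct=adulteration_pct,
        replicate_id=replicate_id,
    )


def generate_study(
    design: StudyDesign,
    bovine_specs: list[FluorophoreSpec] | None = None,
    coconut_specs: list[FluorophoreSpec] | None = None,
    noise: NoiseSpec | None = None,
    grid: EEMGrid | None = None,
) -> EEMDataset:
    """Simulate the full concentration-series study (default: 9 levels x
    10 replicates = 90 scans), each replicate independently seeded from
    ``design.seed``."""
    if design.replicates_per_level < 1:
        raise ValueError("replicates_per_level must be >= 1")
    bovine_specs = bovine_specs if bovine_specs is not None else default_bovine_specs()
    coconut_specs = coconut_specs if coconut_specs is not None else default_coconut_specs()
    noise = noise if noise is not None else NoiseSpec()
    grid = grid if grid is not None else EEMGrid.default()

    master = np.random.default_rng(design.seed)
    seeds = master.integers(0, 2**31 - 1, size=design.n_samples)
    # Replicates are prepared individually, so each fluorophore's effective
    # concentration varies slightly and independently between scans.  This
    # also keeps the sample-mode factor matrix full rank, which trilinear
    # decomposition needs for identifiability (collinear concentration
    # profiles violate the Kruskal uniqueness condition).
    cv = noise.concentration_cv
    n_spec = len(bovine_specs) + len(coconut_specs)
    jitters = master.normal(1.0, cv, size=(design.n_samples, n_spec)) if cv > 0 else None

    bovine = make_pure_profile(bovine_specs, grid)
    coconut = make_pure_profile(coconut_specs, grid)
    samples = []
    i = 0
    for level in design.levels_pct:
        for rep in range(design.replicates_per_level):
            if jitters is not None:
                j = np.clip(jitters[i], 0.1, None)
                bov_i = [replace(s, amplitude=s.amplitude * j[k])
                         for k, s in enumerate(bovine_specs)]
                coco_i = [replace(s, amplitude=s.amplitude * j[len(bovine_specs) + k])
                          for k, s in enumerate(coconut_specs)]
                bovine_i = make_pure_profile(bov_i, grid)
                coconut_i = make_pure_profile(coco_i, grid)
            else:
                bovine_i, coconut_i = bovine, coconut
            samples.append(
                simulate_sample(
                    level, bovine_i, coconut_i, noise, int(seeds[i]), grid=grid,
                    replicate_id=rep,
                )
            )
            i += 1
    return EEMDataset(samples)


# ---------------------------------------------------------------------------
# On-disk format: one CSV matrix per sample plus a JSON manifest.

def save_dataset(dataset: EEMDataset, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = dataset.grid
    manifest = {"global_max": dataset.global_max, "samples": []}
    for s in dataset.samples:
        fname = f"{s.sample_id}.csv"
        header = "," + ",".join(f"{w:g}" for w in grid.emission_nm)
        rows = [header]
        for i, ex in enumerate(grid.excitation_nm):
            rows.append(f"{ex:g}," + ",".join(repr(float(v)) for v in s.intensity[i]))
        (out / fname).write_text("\n".join(rows) + "\n")
        manifest["samples"].append(
            {
                "sample_id": s.sample_id,
                "file": fname,
                "adulteration_pct": s.adulteration_pct,
                "replicate_id": s.replicate_id,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(in_dir) -> EEMDataset:
    from pathlib import Path

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    samples = []
    for entry in manifest["samples"]:
        lines = (src / entry["file"]).read_text().strip().splitlines()
        em = np.array([float(v) for v in lines[0].split(",")[1:]])
        ex, mat = [], []
        for line in lines[1:]:
            parts = line.split(",")
            ex.append(float(parts[0]))
            mat.append([float(v) for v in parts[1:]])
        samples.append(
            EEMSample(
                grid=EEMGrid(np.array(ex), em),
                intensity=np.array(mat),
                adulteration_pct=entry["adulteration_pct"],
                replicate_id=entry["replicate_id"],
                sample_id=entry["sample_id"],
            )
        )
    return EEMDataset(samples)
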