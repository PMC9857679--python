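"""Synthetic hyperspectral cubes and fatty-acid reference tables.

Green-tea storage experiments pair two measurements per sample: a
hyperspectral reflectance cube (900-1700 nm) and a GC-MS fatty-acid
profile.  Neither is publicly available for the study design this package
targets, so this module generates both with the statistical structure the
downstream analysis assumes:

* fatty-acid content decays monotonically over storage, with sharp drops
  between days 30-60 and 120-150 and slight drops elsewhere;
* monomer concentrations share a common latent degradation factor, so
  their regression-coefficient spectra look alike;
* spectra follow an absorbance-like linear mixing model: reflectance is a
  baseline minus concentration-weighted component absorption profiles
  (water, amino acids, caffeine, and a fatty-acid block), plus noise;
* background pixels sit below the 0.1 reflectance masking threshold.

Because the forward model is affine in the concentration vector, a linear
(PLS) calibration can recover the targets -- which is exactly the property
the pipeline's tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from teahsi.errors import InvalidConfigurationError
from teahsi.hsi_io import HyperspectralCube, correct_reflectance, extract_mean_spectrum, segment_roi

SFA_MONOMERS = ("palmitic", "stearic", "arachidic")
UFA_MONOMERS = ("9-hexadecenoic", "oleic", "linoleic", "linolenic", "cis-11-eicosenoic")
MONOMERS = SFA_MONOMERS + UFA_MONOMERS
TOTALS = ("total_sfa", "total_ufa")
ALL_TARGETS = MONOMERS + TOTALS

#: Baseline (day-0 mean) content for each monomer, arbitrary concentration
#: units; relative magnitudes echo typical green-tea fatty-acid profiles
#: (linolenic and linoleic dominate, eicosenoic trace-level).
DEFAULT_BASELINES = {
    "palmitic": 1.20,
    "stearic": 0.35,
    "arachidic": 0.08,
    "9-hexadecenoic": 0.05,
    "oleic": 0.50,
    "linoleic": 1.50,
    "linolenic": 2.80,
    "cis-11-eicosenoic": 0.04,
}

_SHARP_TRANSITIONS = {(30, 60), (120, 150)}


@dataclass(frozen=True)
class DegradationProfile:
    """Mean content trajectory of one fatty acid over storage."""

    fatty_acid_name: str
    baseline_content: float
    content_at_day: dict[int, float]
    within_day_cv: float

    def __post_init__(self) -> None:
        days = sorted(self.content_at_day)
        means = [self.content_at_day[d] for d in days]
        if any(b > a for a, b in zip(means, means[1:])):
            raise InvalidConfigurationError(
                f"{self.fatty_acid_name}: content_at_day must be non-increasing"
            )


@dataclass(frozen=True)
class SpectralLibrary:
    """Component absorption profiles on a common wavelength grid.

    ``component_spectra`` maps component name to a nonnegative absorption
    profile (reflectance-deficit per concentration unit).  The matrix
    constituents (water, amino acids, caffeine) absorb in their known NIR
    overtone bands; the fatty-acid block has its peaks in 1100-1400 nm.
    """

    wavelengths: np.ndarray
    component_spectra: dict[str, np.ndarray]
    background_level: float = 0.62

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise InvalidConfigurationError("wavelength grid must be strictly increasing")
        if wl[0] < 900.0 - 1e-9 or wl[-1] > 1700.0 + 1e-9:
            raise InvalidConfigurationError("wavelength grid must lie within [900, 1700] nm")
        for name, spec in self.component_spectra.items():
            if np.asarray(spec).shape != wl.shape:
                raise InvalidConfigurationError(f"component '{name}' not on the wavelength grid")
            if np.any(np.asarray(spec) < 0):
                raise InvalidConfigurationError(f"component '{name}' has negative absorption")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and noise levels for the generator.

    Defaults reproduce the reference study design: 6 storage days x 15
    samples = 90 samples, 508 bands spanning 900-1700 nm.  ``noise_sd`` is
    per-pixel, per-band reflectance noise; ``within_day_cv`` the relative
    spread of fatty-acid content among same-day samples.
    """

    n_samples_per_day: int = 15
    storage_days: tuple[int, ...] = (0, 30, 60, 90, 120, 150)
    image_shape: tuple[int, int] = (32, 32)
    noise_sd: float = 0.01
    seed: int = 0
    band_count: int = 508
    within_day_cv: float = 0.08
    monomer_correlation: float = 0.7
    sharp_drop: float = 0.35
    slight_drop: float = 0.05
    matrix_cv: float = 0.02
    background_reflectance: float = 0.05
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))

    def __post_init__(self) -> None:
        if self.n_samples_per_day < 1:
            raise InvalidConfigurationError("n_samples_per_day must be >= 1")
        if self.band_count < 8:
            raise InvalidConfigurationError("band_count must be >= 8")
        if len(self.storage_days) < 1 or list(self.storage_days) != sorted(set(self.storage_days)):
            raise InvalidConfigurationError("storage_days must be strictly increasing")
        if not 0 <= self.monomer_correlation <= 1:
            raise InvalidConfigurationError("monomer_correlation must be in [0, 1]")
        for name in ("noise_sd", "within_day_cv", "matrix_cv"):
            if getattr(self, name) < 0:
                raise InvalidConfigurationError(f"{name} must be nonnegative")
        for name in ("sharp_drop", "slight_drop"):
            if not 0 <= getattr(self, name) < 1:
                raise InvalidConfigurationError(f"{name} must be in [0, 1)")
        missing = set(MONOMERS) - set(self.baselines)
        if missing:
            raise InvalidConfigurationError(f"baselines missing monomers: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_day * len(self.storage_days)


@dataclass
class SpectralDataset:
    """Sample x wavelength matrix paired with targets and day labels."""

    spectra: np.ndarray
    wavelengths: np.ndarray
    table: pd.DataFrame

    def target(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(float)

    @property
    def storage_days(self) -> np.ndarray:
        return self.table["storage_day"].to_numpy()


def _gaussian(wl: np.ndarray, center: float, sd: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((wl - center) / sd) ** 2)


def build_spectral_library(band_count: int = 508, seed: int = 0) -> SpectralLibrary:
    """Build component absorption profiles on a 900-1700 nm grid.

    Peaks sit inside the NIR assignment bands established for tea matrices:
    amino acids 1160-1180 nm, water (O-H first overtone) 1450-1500 nm,
    caffeine 1650-1660 nm, and the fatty-acid block within 1100-1400 nm.
    Peak centers are jittered within their bands by ``seed`` so repeated
    studies are not artificially identical; the call is deterministic for a
    fixed seed.
    """
    if band_count < 8:
        raise InvalidConfigurationError("band_count must be >= 8")
    rng = np.random.default_rng(seed)
    wl = np.linspace(900.0, 1700.0, band_count)

    def jitter(lo: float, hi: float, margin: float = 0.15) -> float:
        pad = (hi - lo) * margin
        return rng.uniform(lo + pad, hi - pad)

    water = _gaussian(wl, jitter(1450, 1500), 22.0, 0.22) + _gaussian(wl, 1520.0, 60.0, 0.05)
    amino = _gaussian(wl, jitter(1160, 1180), 12.0, 0.085)
    caffeine = _gaussian(wl, jitter(1650, 1660), 11.0, 0.065)
    # The fatty-acid overtone/combination features are weak and narrow
    # (they are not even visible by eye in tea spectra): a few 10-20 nm
    # wide peaks, so only a small fraction of the 508 bands is informative.
    fatty = (
        _gaussian(wl, jitter(1190, 1240), 8.0, 0.0060)
        + _gaussian(wl, jitter(1290, 1340), 10.0, 0.0048)
        + _gaussian(wl, jitter(1360, 1395), 7.0, 0.0038)
    )
    return SpectralLibrary(
        wavelengths=wl,
        component_spectra={
            "water": water,
            "amino_acids": amino,
            "caffeine": caffeine,
            "fatty_acids": fatty,
        },
    )


def build_default_profiles(config: SimulationConfig) -> list[DegradationProfile]:
    """Degradation trajectories for the eight monomers.

    Each transition between consecutive storage days multiplies the mean by
    ``1 - sharp_drop`` for the 30->60 and 120->150 transitions and by
    ``1 - slight_drop`` otherwise, matching the two-stage freshness loss
    (fresh until ~30 d, sharp aging at 60 d and again at 150 d).
    """
    days = list(config.storage_days)
    profiles = []
    for name in MONOMERS:
        mean = config.baselines[name]
        content = {days[0]: mean}
        for prev, day in zip(days, days[1:]):
            factor = config.sharp_drop if (prev, day) in _SHARP_TRANSITIONS else config.slight_drop
            mean = mean * (1.0 - factor)
            content[day] = mean
        profiles.append(
            DegradationProfile(
                fatty_acid_name=name,
                baseline_content=config.baselines[name],
                content_at_day=content,
                within_day_cv=config.within_day_cv,
            )
        )
    return profiles


def simulate_reference_table(
    config: SimulationConfig, profiles: list[DegradationProfile] | None = None
) -> pd.DataFrame:
    """Simulate the per-sample fatty-acid reference table.

    Per-sample monomer content is ``day_mean * (1 + cv * z)`` truncated at
    zero, where ``z`` is standard normal but shares a common latent factor
    across monomers (correlation ``monomer_correlation``), mimicking a
    sample-level degradation state.  Totals are computed by summation, so
    compositional closure holds exactly.

    Returns a DataFrame with columns ``sample_id``, ``storage_day``, the
    eight monomers, ``total_sfa`` and ``total_ufa``; deterministic for a
    fixed ``config.seed``.
    """
    if profiles is None:
        profiles = build_default_profiles(config)
    by_name = {p.fatty_acid_name: p for p in profiles}
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xFA7)))
    rho = config.monomer_correlation

    rows = []
    for day in config.storage_days:
        for k in range(config.n_samples_per_day):
            g = rng.standard_normal()
            row = {"sample_id": f"d{day:03d}_s{k:02d}", "storage_day": day}
            for name in MONOMERS:
                prof = by_name[name]
                z = rho * g + np.sqrt(1.0 - rho**2) * rng.standard_normal()
                value = prof.content_at_day[day] * (1.0 + prof.within_day_cv * z)
                row[name] = max(value, 0.0)
            rows.append(row)
    table = pd.DataFrame(rows)
    table["total_sfa"] = table[list(SFA_MONOMERS)].sum(axis=1)
    table["total_ufa"] = table[list(UFA_MONOMERS)].sum(axis=1)
    return table


def day_mean_table(config: SimulationConfig) -> pd.DataFrame:
    """Noise-free per-day mean contents (monomers and totals), one row per day."""
    profiles = build_default_profiles(config)
    out = pd.DataFrame({"storage_day": list(config.storage_days)})
    for p in profiles:
        out[p.fatty_acid_name] = [p.content_at_day[d] for d in config.storage_days]
    out["total_sfa"] = out[list(SFA_MONOMERS)].sum(axis=1)
    out["total_ufa"] = out[list(UFA_MONOMERS)].sum(axis=1)
    return out


def foreground_mask(image_shape: tuple[int, int]) -> np.ndarray:
    """Ground-truth elliptical 'leaf pile' region used by the cube simulator."""
    rows, cols = image_shape
    if rows < 8 or cols < 8:
        raise InvalidConfigurationError(
            f"image_shape {image_shape} too small to contain a foreground region (min 8x8)"
        )
    rr, cc = np.mgrid[0:rows, 0:cols]
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    ra, ca = 0.36 * rows, 0.36 * cols
    return ((rr - r0) / ra) ** 2 + ((cc - c0) / ca) ** 2 <= 1.0


def mixture_reflectance(sample_row: pd.Series | dict, library: SpectralLibrary) -> np.ndarray:
    """Noise-free foreground reflectance spectrum for one sample.

    Reflectance deficit is linear in concentration (Beer-Lambert-like):
    baseline minus unit matrix-component absorptions minus the fatty-acid
    block scaled by the sample's total fatty-acid content.
    """
    total_fa = float(sample_row["total_sfa"]) + float(sample_row["total_ufa"])
    spec = library.background_level - (
        library.component_spectra["water"]
        + library.component_spectra["amino_acids"]
        + library.component_spectra["caffeine"]
        + total_fa * library.component_spectra["fatty_acids"]
    )
    return np.clip(spec, 0.0, 1.0)


def simulate_cube(
    sample_row: pd.Series | dict,
    library: SpectralLibrary,
    config: SimulationConfig,
    seed: int | tuple | None = None,
) -> tuple[HyperspectralCube, HyperspectralCube, HyperspectralCube]:
    """Simulate one raw cube plus its white and dark reference cubes.

    Foreground pixels carry the sample's mixture reflectance with per-pixel
    matrix-component variability (``matrix_cv``) and additive Gaussian noise
    (``noise_sd``), clipped to [0, 1]; background pixels sit at
    ``background_reflectance`` (below the 0.1 masking threshold).  The raw
    cube is returned pre-inverse-corrected, i.e. ``raw = dark + R * (white -
    dark)``, so two-point reflectance correction recovers R exactly.
    """
    if seed is None:
        seed = (config.seed, 0xC0BE)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = config.image_shape
    fg = foreground_mask(config.image_shape)
    wl = library.wavelengths
    bands = wl.size

    # Per-sample matrix constituent loadings: nuisance variance uncorrelated
    # with the fatty-acid targets (what wavelength selection must reject).
    loads = {
        name: 1.0 + config.matrix_cv * rng.standard_normal()
        for name in ("water", "amino_acids", "caffeine")
    }
    total_fa = float(sample_row["total_sfa"]) + float(sample_row["total_ufa"])
    deficit = (
        loads["water"] * library.component_spectra["water"]
        + loads["amino_acids"] * library.component_spectra["amino_acids"]
        + loads["caffeine"] * library.component_spectra["caffeine"]
        + total_fa * library.component_spectra["fatty_acids"]
    )
    fg_spectrum = library.background_level - deficit

    reflectance = np.full((rows, cols, bands), config.background_reflectance)
    reflectance[fg] = fg_spectrum
    if config.noise_sd > 0:
        # Band-gain drift of the line-scan detector: one Gaussian draw per
        # band, shared by every pixel of the frame, so — unlike the
        # per-pixel term — it survives ROI averaging.  This is the noise
        # component that limits the mean-spectrum calibration.
        reflectance += 0.5 * config.noise_sd * rng.standard_normal(bands)
        reflectance += config.noise_sd * rng.standard_normal(reflectance.shape)
    reflectance = np.clip(reflectance, 0.0, 1.0)

    ref_noise = min(config.noise_sd, 0.005)
    white_vals = np.clip(0.995 + ref_noise * rng.standard_normal((rows, cols, bands)), 0.9, 1.0)
    dark_vals = np.clip(0.005 + ref_noise * rng.standard_normal((rows, cols, bands)), 0.0, 0.1)

    raw = dark_vals + reflectance * (white_vals - dark_vals)
    make = lambda a: HyperspectralCube(data=a, wavelengths=wl.copy(), corrected=False)
    return make(raw), make(white_vals), make(dark_vals)


def simulate_dataset(
    config: SimulationConfig,
    library: SpectralLibrary | None = None,
    threshold: float = 0.1,
) -> SpectralDataset:
    """Run the full acquisition emulation: cubes -> correction -> ROI -> spectra.

    For each sample in the reference table a cube is simulated, reflectance-
    corrected against its white/dark references, threshold-masked, and the
    ROI mean spectrum extracted.  Per-sample seeds cascade from
    ``config.seed`` via a counter, so the whole dataset is reproducible.
    """
    if library is None:
        library = build_spectral_library(config.band_count, seed=config.seed)
    table = simulate_reference_table(config)
    spectra = np.empty((len(table), config.band_count))
    for i, (_, row) in enumerate(table.iterrows()):
        raw, white, dark = simulate_cube(row, library, config, seed=(config.seed, 1 + i))
        cube = correct_reflectance(raw, white, dark)
        mask = segment_roi(cube, threshold=threshold)
        spectra[i] = extract_mean_spectrum(cube, mask)
    return SpectralDataset(spectra=spectra, wavelengths=library.wavelengths.copy(), table=table)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different global seed."""
    return replace(config, seed=seed)
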