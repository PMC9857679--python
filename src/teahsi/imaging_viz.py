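"""Pixel-wise chemical imaging: concentration maps from a fitted model.

Every foreground pixel's spectrum is pushed through the calibrated PLS (or
CARS-PLS) model, producing a spatial map of predicted concentration — the
"chemical image" that distinguishes hyperspectral analysis from single-spot
NIR spectroscopy.  Background pixels carry NaN and render neutral; a
storage-series of maps shares one colour scale so degradation over time is
visually comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from teahsi.errors import InvalidConfigurationError, WavelengthAlignmentError
from teahsi.hsi_io import HyperspectralCube, RoiMask
from teahsi.pls_core import PLSModel

logger = logging.getLogger(__name__)


@dataclass
class DistributionMap:
    """Per-pixel predicted concentration with background as NaN."""

    values: np.ndarray
    mask: RoiMask
    target_name: str = ""
    calibration_range: tuple[float, float] | None = None

    @property
    def foreground_values(self) -> np.ndarray:
        return self.values[self.mask.mask]

    @property
    def extrapolated_fraction(self) -> float:
        """Fraction of foreground predictions outside the calibration y-range."""
        if self.calibration_range is None:
            return 0.0
        lo, hi = self.calibration_range
        v = self.foreground_values
        return float(np.mean((v < lo) | (v > hi))) if v.size else 0.0


def _model_band_indices(cube: HyperspectralCube, model: PLSModel) -> np.ndarray:
    """Align the model's training wavelengths to cube bands.

    Tolerance is half a band spacing; beyond that the cube cannot supply
    the model's variables and mapping is refused.
    """
    if model.training_wavelength_indices is None:
        if cube.n_bands != model.n_variables:
            raise WavelengthAlignmentError(
                f"cube has {cube.n_bands} bands, full-spectrum model expects {model.n_variables}"
            )
        return np.arange(cube.n_bands)
    idx = np.asarray(model.training_wavelength_indices, int)
    if idx.max(initial=0) >= cube.n_bands:
        raise WavelengthAlignmentError("model wavelength indices exceed cube band count")
    if model.wavelengths_nm is not None:
        spacing = float(np.median(np.diff(cube.wavelengths))) if cube.n_bands > 1 else 1.0
        offsets = np.abs(cube.wavelengths[idx] - model.wavelengths_nm)
        if np.any(offsets > 0.5 * spacing):
            worst = int(np.argmax(offsets))
            raise WavelengthAlignmentError(
                f"cube wavelength {cube.wavelengths[idx[worst]]:.2f} nm differs from model "
                f"wavelength {model.wavelengths_nm[worst]:.2f} nm by more than half a band spacing"
            )
    return idx


def predict_pixelwise(
    cube: HyperspectralCube, mask: RoiMask, model: PLSModel, target_name: str = "",
    calibration_range: tuple[float, float] | None = None,
) -> DistributionMap:
    """Apply the model to every foreground pixel's spectrum.

    Predictions outside the calibration range are kept (extrapolation is
    visible, not hidden) but their fraction is recorded on the map.
    """
    idx = _model_band_indices(cube, model)
    values = np.full(cube.shape[:2], np.nan)
    fg = mask.mask
    if fg.shape != cube.shape[:2]:
        raise WavelengthAlignmentError(
            f"mask shape {fg.shape} does not match cube spatial dims {cube.shape[:2]}"
        )
    spectra = cube.data[fg][:, idx]
    if spectra.size:
        values[fg] = model.predict(spectra)
    dmap = DistributionMap(
        values=values, mask=mask, target_name=target_name, calibration_range=calibration_range
    )
    if calibration_range is not None and dmap.extrapolated_fraction > 0:
        logger.info(
            "%s map: %.1f%% of pixels extrapolate beyond the calibration range",
            target_name, 100 * dmap.extrapolated_fraction,
        )
    return dmap


def series_color_bounds(maps: list[DistributionMap], percentiles=(1.0, 99.0)) -> tuple[float, float]:
    """Shared colour-scale bounds for a storage series of maps.

    Uses the pooled 1st-99th percentile of foreground values so one
    outlier pixel cannot compress the whole series' dynamic range.
    """
    chunks = [m.foreground_values for m in maps if m.foreground_values.size]
    if not chunks:
        raise InvalidConfigurationError("no foreground values in any map")
    pooled = np.concatenate(chunks)
    lo, hi = np.percentile(pooled, percentiles)
    if lo == hi:  # flat series: widen symmetrically so rendering is defined
        lo, hi = lo - 0.5, hi + 0.5
    return float(lo), float(hi)


def render_map(
    dmap: DistributionMap,
    out_path,
    colormap: str = "jet",
    bounds: tuple[float, float] | None = None,
    title: str | None = None,
) -> None:
    """Render a pseudo-colour PNG with a colour bar.

    ``bounds`` (vmin, vmax) should be shared across a storage series so
    equal concentrations get equal colours; background (NaN) renders light
    grey.  Colour lookup is matplotlib's linear normalisation, hence a
    monotone function of concentration within bounds.
    """
    if bounds is not None:
        vmin, vmax = bounds
        if vmin >= vmax:
            raise InvalidConfigurationError(f"invalid colour bounds: min {vmin} >= max {vmax}")
    else:
        fg = dmap.foreground_values
        if fg.size == 0:
            warnings.warn("rendering an all-background map")
            vmin, vmax = 0.0, 1.0
        else:
            vmin, vmax = float(np.nanmin(fg)), float(np.nanmax(fg))
            if vmin == vmax:
                vmin, vmax = vmin - 0.5, vmax + 0.5

    cmap = plt.get_cmap(colormap).copy()
    cmap.set_bad("0.85")
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(dmap.values, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or dmap.target_name)
    fig.colorbar(im, ax=ax, label="predicted content (a.u.)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
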