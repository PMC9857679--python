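"""Generator contracts: degradation structure, mixing model, determinism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from teahsi.errors import InvalidConfigurationError
from teahsi.evaluation import run_pca
from teahsi.hsi_io import correct_reflectance, extract_mean_spectrum, segment_roi
from teahsi.synthetic_data import (
    ALL_TARGETS,
    MONOMERS,
    SFA_MONOMERS,
    UFA_MONOMERS,
    SimulationConfig,
    build_default_profiles,
    build_spectral_library,
    foreground_mask,
    mixture_reflectance,
    simulate_cube,
    simulate_reference_table,
)


class TestSpectralLibrary:
    def test_wavelength_grid_spans_instrument_range(self):
        lib = build_spectral_library(band_count=508, seed=0)
        assert lib.wavelengths.size == 508
        assert lib.wavelengths[0] == pytest.approx(900.0)
        assert lib.wavelengths[-1] == pytest.approx(1700.0)
        assert np.all(np.diff(lib.wavelengths) > 0)

    def test_deterministic_for_fixed_seed(self):
        a = build_spectral_library(508, seed=3)
        b = build_spectral_library(508, seed=3)
        for name in a.component_spectra:
            np.testing.assert_array_equal(a.component_spectra[name], b.component_spectra[name])

    @pytest.mark.parametrize("seed", range(5))
    def test_peak_positions_inside_assignment_bands(self, seed):
        lib = build_spectral_library(508, seed=seed)
        wl = lib.wavelengths

        def argmax_nm(name):
            return wl[np.argmax(lib.component_spectra[name])]

        assert 1450 <= argmax_nm("water") <= 1500
        assert 1160 <= argmax_nm("amino_acids") <= 1180
        assert 1650 <= argmax_nm("caffeine") <= 1660
        fa = lib.component_spectra["fatty_acids"]
        # fatty-acid peak centers lie inside the 1100-1400 nm block; the
        # narrow Gaussian tails may spill a few nm beyond it
        assert 1100 <= wl[np.argmax(fa)] <= 1400
        assert np.all(fa[(wl < 1050) | (wl > 1450)] < 0.05 * fa.max())

    def test_component_spectra_nonnegative(self):
        lib = build_spectral_library(256, seed=1)
        for spec in lib.component_spectra.values():
            assert np.all(spec >= 0)

    def test_too_few_bands_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            build_spectral_library(band_count=7)


class TestReferenceTable:
    def test_default_design_is_90_samples_15_per_day(self):
        table = simulate_reference_table(SimulationConfig())
        assert len(table) == 90
        assert table.groupby("storage_day").size().eq(15).all()
        assert set(ALL_TARGETS) <= set(table.columns)

    def test_totals_close_compositionally(self, small_table):
        np.testing.assert_allclose(
            small_table["total_sfa"],
            small_table[list(SFA_MONOMERS)].sum(axis=1),
            rtol=0,
            atol=0,
        )
        np.testing.assert_allclose(
            small_table["total_ufa"],
            small_table[list(UFA_MONOMERS)].sum(axis=1),
            rtol=0,
            atol=0,
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_day_means_monotonically_decreasing(self, seed):
        table = simulate_reference_table(SimulationConfig(seed=seed))
        means = table.groupby("storage_day")[list(ALL_TARGETS)].mean()
        profile_means = {
            p.fatty_acid_name: p.content_at_day
            for p in build_default_profiles(SimulationConfig(seed=seed))
        }
        # noise-free trajectories are non-increasing by construction ...
        for name, content in profile_means.items():
            days = sorted(content)
            assert all(content[a] >= content[b] for a, b in zip(days, days[1:]))
        # ... and empirical day means track them closely enough to decrease too
        for col in ALL_TARGETS:
            assert (np.diff(means[col].to_numpy()) < 0).all()

    def test_sharp_vs_slight_drop_schedule(self):
        cfg = SimulationConfig(sharp_drop=0.35, slight_drop=0.05)
        prof = {p.fatty_acid_name: p.content_at_day for p in build_default_profiles(cfg)}
        c = prof["palmitic"]
        assert c[60] / c[30] == pytest.approx(0.65)
        assert c[150] / c[120] == pytest.approx(0.65)
        assert c[30] / c[0] == pytest.approx(0.95)
        assert c[90] / c[60] == pytest.approx(0.95)

    def test_zero_cv_gives_identical_samples_within_day(self):
        table = simulate_reference_table(SimulationConfig(within_day_cv=0.0))
        spread = table.groupby("storage_day")[list(MONOMERS)].std()
        assert np.allclose(spread.to_numpy(), 0.0)

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(seed=11)
        pd.testing.assert_frame_equal(
            simulate_reference_table(cfg), simulate_reference_table(cfg)
        )


class TestSimulateCube:
    def test_zero_noise_mean_spectrum_is_exact_mixture(self, small_config, small_table):
        cfg = replace(small_config, noise_sd=0.0, matrix_cv=0.0)
        lib = build_spectral_library(cfg.band_count, seed=cfg.seed)
        row = small_table.iloc[0]
        raw, white, dark = simulate_cube(row, lib, cfg, seed=5)
        cube = correct_reflectance(raw, white, dark)
        mask = segment_roi(cube, threshold=0.1)
        np.testing.assert_array_equal(mask.mask, foreground_mask(cfg.image_shape))
        spectrum = extract_mean_spectrum(cube, mask)
        np.testing.assert_allclose(spectrum, mixture_reflectance(row, lib), rtol=1e-10)

    def test_background_pixels_below_masking_threshold(self, small_config, small_table):
        lib = build_spectral_library(small_config.band_count, seed=small_config.seed)
        raw, white, dark = simulate_cube(small_table.iloc[3], lib, small_config, seed=2)
        cube = correct_reflectance(raw, white, dark)
        bg = ~foreground_mask(small_config.image_shape)
        assert np.all(cube.band_mean_image()[bg] < 0.1)

    def test_equal_contents_and_seed_give_identical_cubes(self, small_config, small_table):
        lib = build_spectral_library(small_config.band_count, seed=small_config.seed)
        row = small_table.iloc[1]
        raw1, w1, d1 = simulate_cube(row, lib, small_config, seed=9)
        raw2, w2, d2 = simulate_cube(row.copy(), lib, small_config, seed=9)
        np.testing.assert_array_equal(raw1.data, raw2.data)
        np.testing.assert_array_equal(w1.data, w2.data)
        np.testing.assert_array_equal(d1.data, d2.data)

    def test_image_too_small_rejected(self, small_table):
        cfg = SimulationConfig(image_shape=(4, 4), band_count=16)
        lib = build_spectral_library(16, seed=0)
        with pytest.raises(InvalidConfigurationError):
            simulate_cube(small_table.iloc[0], lib, cfg)

    def test_linear_forward_model_affine_in_concentration(self, small_config):
        """Corrected mean spectra respond affinely to the target vector."""
        cfg = replace(small_config, noise_sd=0.0, matrix_cv=0.0)
        lib = build_spectral_library(cfg.band_count, seed=cfg.seed)
        base = {m: 1.0 for m in MONOMERS}
        rows = []
        for scale in (0.5, 1.0, 1.5):
            row = {m: v * scale for m, v in base.items()}
            row["total_sfa"] = sum(row[m] for m in SFA_MONOMERS)
            row["total_ufa"] = sum(row[m] for m in UFA_MONOMERS)
            rows.append(mixture_reflectance(row, lib))
        # equally spaced concentrations -> equally spaced spectra
        np.testing.assert_allclose(rows[1] - rows[0], rows[2] - rows[1], atol=1e-12)


class TestDayClusterStructure:
    def test_pca_separates_fresh_from_aged(self, default_dataset):
        """Spectra of day-0 and day-150 samples form separated clusters."""
        from sklearn.metrics import silhouette_score

        days = default_dataset.storage_days
        keep = (days == 0) | (days == 150)
        scores, _, _ = run_pca(default_dataset.spectra[keep], n_pc=2)
        assert silhouette_score(scores, days[keep]) > 0
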