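"""Cube I/O, reflectance correction, ROI masking and spectrum extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teahsi.errors import (
    DegenerateReferenceError,
    DimensionError,
    EmptyRoiError,
    FormatError,
)
from teahsi.hsi_io import (
    HyperspectralCube,
    RoiMask,
    correct_reflectance,
    extract_mean_spectrum,
    read_cube,
    segment_roi,
    write_cube,
)


def make_cube(data, corrected=False):
    data = np.asarray(data, float)
    wl = np.linspace(900, 1700, data.shape[2])
    return HyperspectralCube(data=data, wavelengths=wl, corrected=corrected)


@pytest.fixture
def references():
    rng = np.random.default_rng(0)
    white = make_cube(0.95 + 0.02 * rng.random((5, 6, 8)))
    dark = make_cube(0.02 * rng.random((5, 6, 8)))
    return white, dark


class TestCorrectReflectance:
    def test_raw_equal_to_references_hits_bounds(self, references):
        white, dark = references
        np.testing.assert_allclose(
            correct_reflectance(make_cube(white.data), white, dark).data, 1.0
        )
        np.testing.assert_allclose(
            correct_reflectance(make_cube(dark.data), white, dark).data, 0.0
        )

    def test_midpoint_maps_to_half(self, references):
        white, dark = references
        mid = make_cube((white.data + dark.data) / 2)
        np.testing.assert_allclose(correct_reflectance(mid, white, dark).data, 0.5)

    def test_affine_in_raw(self, references):
        """Correcting a convex combination equals combining corrections."""
        white, dark = references
        rng = np.random.default_rng(1)
        a = make_cube(rng.uniform(0.1, 0.9, white.shape))
        b = make_cube(rng.uniform(0.1, 0.9, white.shape))
        lam = 0.3
        mix = make_cube(lam * a.data + (1 - lam) * b.data)
        expect = (
            lam * correct_reflectance(a, white, dark).data
            + (1 - lam) * correct_reflectance(b, white, dark).data
        )
        np.testing.assert_allclose(
            correct_reflectance(mix, white, dark).data, expect, atol=1e-12
        )

    def test_shape_mismatch_rejected(self, references):
        white, dark = references
        with pytest.raises(DimensionError):
            correct_reflectance(make_cube(np.zeros((5, 6, 9))), white, dark)

    def test_degenerate_reference_names_band(self):
        white = make_cube(np.ones((2, 2, 4)))
        dark = make_cube(np.ones((2, 2, 4)))  # coincides everywhere
        with pytest.raises(DegenerateReferenceError, match="band 0"):
            correct_reflectance(make_cube(np.ones((2, 2, 4))), white, dark)

    def test_result_clipped_and_flagged(self, references):
        white, dark = references
        hot = make_cube(white.data * 1.5)  # brighter than the white tile
        out = correct_reflectance(hot, white, dark)
        assert out.corrected
        assert out.data.max() <= 1.0 and out.data.min() >= 0.0


class TestSegmentRoi:
    def test_uniform_below_threshold_is_empty_roi(self):
        cube = make_cube(np.full((4, 4, 8), 0.05), corrected=True)
        with pytest.raises(EmptyRoiError):
            segment_roi(cube, threshold=0.1)

    def test_exact_threshold_pixel_is_background(self):
        data = np.full((2, 2, 4), 0.10)
        data[0, 0] = 0.5
        mask = segment_roi(make_cube(data, corrected=True), threshold=0.1)
        assert mask.mask[0, 0]
        assert mask.mask.sum() == 1  # the 0.10 pixels are strictly excluded

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        cube = make_cube(rng.uniform(0, 1, (6, 6, 10)), corrected=True)
        lo = segment_roi(cube, threshold=0.2).mask
        hi = segment_roi(cube, threshold=0.5).mask
        assert np.all(lo[hi])  # raising threshold never adds pixels

    @given(thr=st.floats(0.05, 0.6))
    @settings(deadline=None, max_examples=25)
    def test_idempotent_and_consistent_with_band_mean(self, thr):
        rng = np.random.default_rng(3)
        cube = make_cube(rng.uniform(0, 1, (5, 5, 7)), corrected=True)
        mask = segment_roi(cube, threshold=thr)
        np.testing.assert_array_equal(mask.mask, cube.band_mean_image() > thr)
        assert mask.threshold_used == thr


class TestExtractMeanSpectrum:
    def test_single_pixel_roi_returns_that_spectrum(self):
        rng = np.random.default_rng(4)
        cube = make_cube(rng.random((3, 3, 6)))
        m = np.zeros((3, 3), bool)
        m[1, 2] = True
        np.testing.assert_array_equal(
            extract_mean_spectrum(cube, RoiMask(m)), cube.data[1, 2]
        )

    def test_mean_linearity_over_disjoint_masks(self):
        rng = np.random.default_rng(5)
        cube = make_cube(rng.random((4, 4, 5)))
        m1 = np.zeros((4, 4), bool)
        m2 = np.zeros((4, 4), bool)
        m1[:2] = True
        m2[2:] = True  # equal sizes, disjoint
        s_union = extract_mean_spectrum(cube, RoiMask(m1 | m2))
        s_halves = 0.5 * (
            extract_mean_spectrum(cube, RoiMask(m1)) + extract_mean_spectrum(cube, RoiMask(m2))
        )
        np.testing.assert_allclose(s_union, s_halves, atol=1e-14)

    def test_empty_mask_rejected(self):
        cube = make_cube(np.ones((2, 2, 3)))
        with pytest.raises(EmptyRoiError):
            extract_mean_spectrum(cube, RoiMask(np.zeros((2, 2), bool)))

    def test_commutes_with_correction_under_uniform_references(self):
        rng = np.random.default_rng(6)
        raw = make_cube(rng.uniform(0.1, 0.8, (4, 4, 6)))
        white = make_cube(np.full((4, 4, 6), 0.9))
        dark = make_cube(np.full((4, 4, 6), 0.1))
        m = RoiMask(np.ones((4, 4), bool))
        corrected_mean = extract_mean_spectrum(correct_reflectance(raw, white, dark), m)
        mean_corrected = (extract_mean_spectrum(raw, m) - 0.1) / 0.8
        np.testing.assert_allclose(corrected_mean, mean_corrected, atol=1e-12)


class TestCubeRoundTrip:
    @pytest.mark.parametrize("fmt", ["bil", "bsq", "h5"])
    def test_round_trip_identity(self, tmp_path, fmt):
        rng = np.random.default_rng(7)
        cube = make_cube(rng.random((5, 7, 11)), corrected=True)
        path = tmp_path / ("cube.h5" if fmt == "h5" else f"cube.{fmt}")
        write_cube(cube, path, interleave=fmt if fmt != "h5" else "bil")
        back = read_cube(path)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)
        assert back.corrected == cube.corrected

    def test_bil_and_bsq_agree(self, tmp_path):
        rng = np.random.default_rng(8)
        cube = make_cube(rng.random((4, 6, 9)))
        write_cube(cube, tmp_path / "a.bil", interleave="bil")
        write_cube(cube, tmp_path / "b.bsq", interleave="bsq")
        np.testing.assert_array_equal(
            read_cube(tmp_path / "a.bil").data, read_cube(tmp_path / "b.bsq").data
        )

    def test_truncated_binary_detected(self, tmp_path):
        cube = make_cube(np.random.default_rng(9).random((3, 4, 8)))
        path = tmp_path / "cube.bil"
        write_cube(cube, path)
        blob = path.read_bytes()
        path.write_bytes(blob[: len(blob) - 8])  # drop one float -> 507-of-508 analogue
        with pytest.raises(FormatError, match="size"):
            read_cube(path)

    def test_malformed_header_fields_reported(self, tmp_path):
        cube = make_cube(np.random.default_rng(10).random((3, 4, 8)))
        path = tmp_path / "cube.bil"
        write_cube(cube, path)
        hdr = path.with_suffix(".bil.hdr")
        text = hdr.read_text()
        hdr.write_text(text.replace("interleave = bil", "interleave = bip"))
        with pytest.raises(FormatError, match="interleave"):
            read_cube(path)
        hdr.write_text(text.replace("bands = 8", "bands = eight"))
        with pytest.raises(FormatError, match="bands"):
            read_cube(path)

    def test_reading_header_path_works(self, tmp_path):
        cube = make_cube(np.random.default_rng(11).random((2, 3, 5)))
        write_cube(cube, tmp_path / "c.bsq", interleave="bsq")
        back = read_cube(tmp_path / "c.bsq.hdr")
        np.testing.assert_array_equal(back.data, cube.data)
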