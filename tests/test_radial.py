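"""Tests of center-of-mass and radial-histogram feature extraction."""

import numpy as np
import pytest

import cemradial as cr
from cemradial.errors import DataError, DegenerateInputError
from cemradial.radial import (
    build_feature_matrix,
    center_of_mass,
    class_average_profile,
    concatenate_histograms,
    radial_histogram,
)


def brute_force_histogram(image, center, n_bands, r_max=None):
    """Per-pixel distance binning oracle: explicit double loop."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if r_max is None:
        r_max = max(
            np.hypot(center[0] - r, center[1] - c)
            for r in (0, h - 1)
            for c in (0, w - 1)
        )
    width = r_max / n_bands
    mass = np.zeros(n_bands)
    area = np.zeros(n_bands)
    for r in range(h):
        for c in range(w):
            d = np.hypot(r - center[0], c - center[1])
            if d > r_max:
                continue
            b = min(int(d / width), n_bands - 1)
            mass[b] += image[r, c]
            area[b] += 1
    values = np.zeros(n_bands)
    np.divide(mass, area, out=values, where=area > 0)
    if values.sum() > 0:
        values = values / values.sum()
    return values, mass


class TestCenterOfMass:
    def test_single_nonzero_pixel(self):
        img = np.zeros((10, 10))
        img[7, 3] = 5.0
        assert center_of_mass(img, np.ones((10, 10), bool)) == (7.0, 3.0)

    def test_two_equal_pixels_split_the_difference(self):
        img = np.zeros((4, 4))
        img[1, 1] = img[1, 2] = 2.0
        assert center_of_mass(img, np.ones((4, 4), bool)) == (1.0, 1.5)

    def test_matches_brute_force_weighted_mean(self, rng):
        img = rng.random((9, 9))
        mask = rng.random((9, 9)) > 0.3
        mask[4, 4] = True
        total = rsum = csum = 0.0
        for r in range(9):
            for c in range(9):
                if mask[r, c]:
                    total += img[r, c]
                    rsum += img[r, c] * r
                    csum += img[r, c] * c
        got = center_of_mass(img, mask)
        assert abs(got[0] - rsum / total) < 1e-12
        assert abs(got[1] - csum / total) < 1e-12

    def test_masked_pixels_are_excluded(self):
        img = np.ones((5, 5))
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        assert center_of_mass(img, mask) == (0.0, 0.0)

    def test_all_zero_mask_region_raises(self):
        img = np.zeros((5, 5))
        with pytest.raises(DegenerateInputError):
            center_of_mass(img, np.ones((5, 5), bool))


class TestRadialHistogram:
    def test_constant_image_gives_uniform_values(self):
        h = radial_histogram(np.ones((15, 15)), (7, 7), 4)
        nonempty = h.values > 0
        assert np.allclose(h.values[nonempty], 1 / nonempty.sum())

    def test_all_mass_at_center_pixel(self):
        img = np.zeros((11, 11))
        img[5, 5] = 3.0
        h = radial_histogram(img, (5, 5), 6)
        assert h.values[0] == 1.0
        assert np.all(h.values[1:] == 0)

    def test_matches_brute_force_oracle_21x21(self, rng):
        img = rng.random((21, 21))
        h = radial_histogram(img, (10, 10), 5)
        expected, _ = brute_force_histogram(img, (10, 10), 5)
        assert np.abs(h.values - expected).max() < 1e-12

    def test_off_center_and_rectangular_against_oracle(self, rng):
        img = rng.random((12, 19))
        h = radial_histogram(img, (3.5, 11.2), 7)
        expected, _ = brute_force_histogram(img, (3.5, 11.2), 7)
        assert np.abs(h.values - expected).max() < 1e-12

    def test_conservation_of_integer_mass_is_exact(self, rng):
        img = rng.integers(0, 4000, size=(25, 25)).astype(np.uint16)
        h = radial_histogram(img, (12, 12), 8)
        assert h.total_mass == float(img.sum())

    def test_scale_invariance_of_values(self, rng):
        img = rng.random((16, 16)) + 0.1
        h1 = radial_histogram(img, (8, 8), 6)
        h2 = radial_histogram(3.5 * img, (8, 8), 6)
        assert np.allclose(h1.values, h2.values)
        assert np.isclose(h2.total_mass, 3.5 * h1.total_mass)

    def test_rotation_invariance_for_centered_input(self, rng):
        # odd-sized image rotated 90 degrees about its center permutes
        # pixels within annuli, leaving the histogram unchanged
        img = rng.random((17, 17))
        h1 = radial_histogram(img, (8, 8), 5)
        h2 = radial_histogram(np.rot90(img), (8, 8), 5)
        assert np.allclose(h1.values, h2.values, atol=1e-12)

    def test_unit_sum_and_band_edges(self, rng):
        img = rng.random((30, 30))
        h = radial_histogram(img, (10, 20), 9)
        assert np.isclose(h.values.sum(), 1.0)
        assert h.band_edges[0] == 0.0
        assert np.all(np.diff(h.band_edges) > 0)
        assert len(h.band_edges) == 10

    def test_area_only_normalization_mode(self, rng):
        img = rng.random((14, 14))
        h = radial_histogram(img, (7, 7), 4, normalize="area")
        assert not np.isclose(h.values.sum(), 1.0)  # raw per-area masses

    def test_excess_bands_are_empty_not_fatal(self, rng):
        img = rng.random((16, 16))
        h = radial_histogram(img, (8, 8), 64)
        assert np.isclose(h.values.sum(), 1.0)
        assert (h.values == 0).sum() > 0

    def test_center_outside_image_rejected(self):
        with pytest.raises(DataError):
            radial_histogram(np.ones((8, 8)), (9.0, 4.0), 3)

    def test_fewer_than_two_bands_rejected(self):
        with pytest.raises(DataError):
            radial_histogram(np.ones((8, 8)), (4, 4), 1)


class TestConcatenation:
    def _hist(self, values, channel):
        values = np.asarray(values, float)
        return cr.RadialHistogram(
            values=values,
            band_edges=np.linspace(0, 10, len(values) + 1),
            center=(5.0, 5.0),
            channel=channel,
            total_mass=1.0,
        )

    def test_blocks_keep_their_unit_sums(self):
        d = self._hist([0.5, 0.3, 0.1, 0.1], "density")
        c = self._hist([0.25, 0.25, 0.25, 0.25], "contrast")
        vec = concatenate_histograms(d, c)
        assert len(vec) == 8
        assert np.isclose(vec[:4].sum(), 1.0)
        assert np.isclose(vec[4:].sum(), 1.0)

    def test_slicing_recovers_inputs(self):
        d = self._hist([0.7, 0.2, 0.1], "density")
        c = self._hist([0.1, 0.2, 0.7], "contrast")
        vec = concatenate_histograms(d, c)
        assert np.array_equal(vec[:3], d.values)
        assert np.array_equal(vec[3:], c.values)

    def test_mismatched_band_counts_rejected(self):
        d = self._hist([0.5, 0.5], "density")
        c = self._hist([0.4, 0.3, 0.3], "contrast")
        with pytest.raises(DataError):
            concatenate_histograms(d, c)


class TestClassAverageProfile:
    def _hist(self, values):
        values = np.asarray(values, float)
        return cr.RadialHistogram(
            values=values,
            band_edges=np.linspace(0, 10, len(values) + 1),
            center=(0.0, 0.0),
            channel="density",
            total_mass=1.0,
        )

    def test_identical_histograms_average_to_member(self):
        hists = [self._hist([0.6, 0.4])] * 3 + [self._hist([0.2, 0.8])] * 2
        neg, pos = class_average_profile(hists, [0, 0, 0, 1, 1])
        assert np.allclose(neg, [0.6, 0.4])
        assert np.allclose(pos, [0.2, 0.8])

    def test_mean_of_opposite_corners(self):
        hists = [self._hist([1.0, 0.0]), self._hist([0.0, 1.0])]
        neg, _pos = class_average_profile(hists + hists, [0, 0, 1, 1])
        assert np.allclose(neg, [0.5, 0.5])

    def test_empty_class_rejected(self):
        with pytest.raises(DataError):
            class_average_profile([self._hist([1.0, 0.0])], [1])

    def test_malignant_profile_dominates_band_zero(self, small_cohort):
        """On synthetic cohorts the malignant class mean has a larger
        innermost-band value than the benign mean."""
        kept, labels, _ = cr.exclusion_filter(
            small_cohort.cases, "malignant_vs_benign"
        )
        hists = [cr.case_histograms(c, 16)["density"] for c in kept]
        neg, pos = class_average_profile(hists, labels)
        assert pos[0] > neg[0]


class TestFeatureMatrix:
    def test_concatenated_blocks_equal_single_channel_matrices(self, small_cohort):
        kept, labels, _ = cr.exclusion_filter(
            small_cohort.cases, "malignant_vs_benign"
        )
        fd = build_feature_matrix(kept, labels, "density", 8)
        fc = build_feature_matrix(kept, labels, "contrast", 8)
        fcat = build_feature_matrix(kept, labels, "concatenated", 8)
        assert fcat.X.shape == (len(kept), 16)
        assert np.array_equal(fcat.X[:, :8], fd.X)
        assert np.array_equal(fcat.X[:, 8:], fc.X)

    def test_unknown_feature_set_rejected(self, small_cohort):
        with pytest.raises(DataError):
            build_feature_matrix(small_cohort.cases[:4], [0, 0, 1, 1], "wavelet", 8)
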