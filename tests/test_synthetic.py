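"""Tests of the synthetic CEM cohort generator."""

import numpy as np
import pandas as pd
import pytest

import cemradial as cr
from cemradial.config import CohortConfig
from cemradial.errors import ConfigurationError, DataError
from cemradial.synthetic import (
    draw_class_labels,
    generate_cohort,
    generate_covariates,
    generate_lesion_image,
    write_cohort,
)


class TestConfigInvariants:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(class_mix={"benign": 0.5, "high_risk": 0.1, "atypia": 0.1, "malignant": 0.1})

    def test_malignant_decay_must_exceed_benign(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(decay_benign=0.08, decay_malignant=0.04)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_findings": 1},
            {"image_size": 8},
            {"decay_benign": -0.01, "decay_malignant": 0.08},
            {"noise_sd": -1.0},
            {"invasive_fraction": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            CohortConfig(**kwargs)


class TestLesionImage:
    def test_noiseless_profile_decreases_along_rays(self):
        """With no noise and no background, intensity is non-increasing
        with distance from the lesion center along any ray."""
        cfg = CohortConfig(
            image_size=64,
            noise_sd=0.0,
            background_mean=0.0,
            background_texture_amplitude=0.0,
            center_jitter_frac=0.0,
            decay_jitter_sd=0.0,
        )
        img, _ = generate_lesion_image(
            "benign", "density", cfg, np.random.default_rng(0)
        )
        c = 32
        rays = [img[c, c:], img[c, c::-1], img[c:, c], img[c::-1, c]]
        for ray in rays:
            assert np.all(np.diff(ray.astype(int)) <= 0)

    def test_seeded_determinism(self):
        cfg = CohortConfig(image_size=48)
        img1, cont1 = generate_lesion_image(
            "malignant", "contrast", cfg, np.random.default_rng(5), invasive=True
        )
        img2, cont2 = generate_lesion_image(
            "malignant", "contrast", cfg, np.random.default_rng(5), invasive=True
        )
        assert np.array_equal(img1, img2)
        assert np.array_equal(cont1, cont2)

    def test_invalid_class_rejected(self):
        cfg = CohortConfig(image_size=32)
        with pytest.raises(ConfigurationError):
            generate_lesion_image("weird", "density", cfg, np.random.default_rng(0))
        with pytest.raises(ConfigurationError):
            generate_lesion_image("benign", "sideways", cfg, np.random.default_rng(0))

    def test_malignant_more_centrally_concentrated(self):
        """Mean fraction of total intensity within 10 px of the lesion
        center is strictly greater for malignant than benign findings
        (200 lesions per class, default decays)."""
        cfg = CohortConfig(image_size=128, center_jitter_frac=0.0)
        fractions = {}
        for label in ("benign", "malignant"):
            rng = np.random.default_rng(99)
            vals = []
            for _ in range(200):
                img, _ = generate_lesion_image(label, "density", cfg, rng)
                img = img.astype(float)
                rows = np.arange(128)[:, None]
                cols = np.arange(128)[None, :]
                d = np.hypot(rows - 64.0, cols - 64.0)
                vals.append(img[d < 10].sum() / img.sum())
            fractions[label] = np.mean(vals)
        assert fractions["malignant"] > fractions["benign"]

    def test_contour_approximates_half_maximum(self):
        cfg = CohortConfig(
            image_size=128,
            noise_sd=0.0,
            background_mean=0.0,
            background_texture_amplitude=0.0,
            center_jitter_frac=0.0,
            decay_jitter_sd=0.0,
        )
        img, contour = generate_lesion_image(
            "malignant", "density", cfg, np.random.default_rng(2)
        )
        peak = img.astype(float).max()
        # sample image intensity at contour vertices: close to half max
        vals = [img[int(round(y)), int(round(x))] for x, y in contour]
        assert np.allclose(np.mean(vals), peak / 2, rtol=0.1)


class TestCovariates:
    def test_null_age_link_gives_equal_distributions(self):
        """With age_or_per_year = 1 the age distribution is independent
        of class (no location shift)."""
        from scipy import stats

        cfg = CohortConfig(n_findings=2000, age_or_per_year=1.0)
        labels, _ = draw_class_labels(cfg, np.random.default_rng(3))
        cov = generate_covariates(labels, cfg, np.random.default_rng(4))
        mal = cov.loc[cov["class"] == "malignant", "age"]
        rest = cov.loc[cov["class"] != "malignant", "age"]
        assert stats.ttest_ind(mal, rest).pvalue > 0.01

    def test_age_or_recovered_by_logistic_fit(self):
        """The configured OR of 1.07 per year is recovered within the
        study's reported interval at n = 2000."""
        cfg = CohortConfig(n_findings=2000, seed=11)
        labels, _ = draw_class_labels(cfg, np.random.default_rng(11))
        cov = generate_covariates(labels, cfg, np.random.default_rng(12))
        y = (cov["class"] == "malignant").astype(int).to_numpy()
        fit = cr.fit_logistic(y, cov[["age"]], mode="univariable")
        assert 1.04 <= fit.odds_ratio("age") <= 1.10

    def test_menopause_tracks_age(self):
        cfg = CohortConfig(n_findings=1000)
        labels, _ = draw_class_labels(cfg, np.random.default_rng(0))
        cov = generate_covariates(labels, cfg, np.random.default_rng(1))
        post = cov.loc[cov["menopause"] == "post", "age"]
        pre = cov.loc[cov["menopause"] == "pre", "age"]
        assert post.mean() > pre.mean() + 10

    def test_empty_label_list_rejected(self):
        with pytest.raises(DataError):
            generate_covariates([], CohortConfig(), np.random.default_rng(0))

    def test_fixed_seed_reproduces_table(self):
        cfg = CohortConfig(n_findings=50)
        labels, _ = draw_class_labels(cfg, np.random.default_rng(8))
        t1 = generate_covariates(labels, cfg, np.random.default_rng(9))
        t2 = generate_covariates(labels, cfg, np.random.default_rng(9))
        pd.testing.assert_frame_equal(t1, t2)


class TestCohort:
    def test_exact_mix_reproduces_reference_counts(self):
        """A 159-finding cohort with the default mix allocates exactly
        70 benign, 10 high-risk, 8 atypia, 71 malignant, 51 invasive."""
        cfg = CohortConfig(n_findings=159, image_size=64, seed=0)
        labels, invasive = draw_class_labels(cfg, np.random.default_rng(0))
        counts = pd.Series(labels).value_counts()
        assert counts["benign"] == 70
        assert counts["high_risk"] == 10
        assert counts["atypia"] == 8
        assert counts["malignant"] == 71
        assert sum(invasive) == 51

    def test_multinomial_mix_varies_but_sums(self):
        cfg = CohortConfig(n_findings=159, image_size=64, exact_mix=False)
        totals = []
        for seed in range(5):
            labels, _ = draw_class_labels(cfg, np.random.default_rng(seed))
            assert len(labels) == 159
            totals.append(labels.count("malignant"))
        assert len(set(totals)) > 1  # actually random
        assert abs(np.mean(totals) - 71) < 15

    def test_cohort_determinism(self, small_config, small_cohort):
        again = generate_cohort(small_config)
        for a, b in zip(small_cohort.cases, again.cases):
            assert np.array_equal(a.density_image, b.density_image)
            assert np.array_equal(a.contrast_image, b.contrast_image)
            assert np.array_equal(a.contour, b.contour)
            assert a.age == b.age
        pd.testing.assert_frame_equal(small_cohort.manifest, again.manifest)

    def test_invasive_flag_only_on_malignant(self, small_cohort):
        for case in small_cohort.cases:
            assert (case.invasive_flag is not None) == (
                case.class_label == "malignant"
            )


class TestWriteCohort:
    def test_round_trip_is_bit_identical(self, small_cohort, tmp_path):
        manifest = write_cohort(small_cohort, tmp_path)
        cases = cr.read_cohort(manifest)
        assert len(cases) == len(small_cohort.cases)
        for orig, read in zip(small_cohort.cases, cases):
            assert np.array_equal(orig.density_image, read.density_image)
            assert np.array_equal(orig.contrast_image, read.contrast_image)
            assert np.allclose(orig.contour, read.contour)
            assert orig.class_label == read.class_label
            assert orig.invasive_flag == read.invasive_flag
            assert orig.age == pytest.approx(read.age)

    def test_manifest_row_count(self, small_cohort, tmp_path):
        manifest = write_cohort(small_cohort, tmp_path)
        assert len(pd.read_csv(manifest)) == small_cohort.config_used.n_findings

    def test_missing_file_detected_by_name(self, small_cohort, tmp_path):
        manifest = write_cohort(small_cohort, tmp_path)
        victim = small_cohort.manifest.iloc[3]
        (tmp_path / victim["density_path"]).unlink()
        with pytest.raises(DataError, match=victim["case_id"]):
            cr.validate_manifest(manifest)
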