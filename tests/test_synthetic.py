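"""Synthetic cohort generator: label rule, moments, determinism, volumes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndfusion import CohortConfig, derive_nd_label, derive_nihss_correlations, generate_cohort
from ndfusion.synthetic import (NEGATIVE_STATS, POSITIVE_STATS, clipped_normal_moments,
                                records_to_frame, render_volume, sample_clinical,
                                standardize_tabular, tabular_matrix,
                                train_feature_stats, normalize_volume)

SMALL_VOL = dict(volume_shape=(8, 16, 16), lesion_radius_range=(1.0, 2.0))


class TestNdLabelRule:
    @pytest.mark.parametrize("adm,peak,expected", [
        (5, 7, 1),    # exactly 2-point rise: deterioration
        (5, 6, 0),    # 1-point rise is below the threshold
        (4, 4, 0),    # no change
        (0, 10, 1),
        (3, 4.99, 0),
    ])
    def test_two_point_rise_defines_deterioration(self, adm, peak, expected):
        assert derive_nd_label(adm, peak) == expected

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            derive_nd_label(-1, 3)

    @given(adm=st.floats(0, 42), rise=st.floats(0, 20))
    @settings(max_examples=200, derandomize=True)
    def test_label_equals_threshold_indicator(self, adm, rise):
        assert derive_nd_label(adm, adm + rise) == int((adm + rise) - adm >= 2)


class TestImpliedCorrelation:
    def test_published_positive_class_sds(self):
        # admission 2.23, discharge 2.48, change 2.39
        assert derive_nihss_correlations(2.23, 2.48, 2.39) == pytest.approx(0.4892, abs=1e-3)

    def test_published_negative_class_sds(self):
        assert derive_nihss_correlations(3.11, 2.58, 1.66) == pytest.approx(0.8458, abs=1e-3)

    def test_independence_case(self):
        assert derive_nihss_correlations(1, 1, np.sqrt(2)) == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_sds_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            derive_nihss_correlations(1.0, 1.0, 10.0)

    def test_monte_carlo_roundtrip(self):
        """Simulating with the derived correlation reproduces the change SD
        (pre-clipping oracle for the identity itself)."""
        rho = derive_nihss_correlations(2.23, 2.48, 2.39)
        rng = np.random.default_rng(0)
        cov = np.array([[2.23 ** 2, rho * 2.23 * 2.48], [rho * 2.23 * 2.48, 2.48 ** 2]])
        adm, dis = rng.multivariate_normal([5.02, 6.75], cov, size=400_000).T
        assert (dis - adm).std() == pytest.approx(2.39, abs=0.02)


class TestClippedNormalCalibration:
    @pytest.mark.parametrize("mu,sd,lo,hi", [
        (13.05, 6.71, 1.0, 90.0),     # negative-class stay length
        (4.91, 3.11, 0.0, 42.0),      # negative-class admission NIHSS
        (6.75, 2.48, 0.0, 42.0),
    ])
    def test_closed_form_moments_match_monte_carlo(self, mu, sd, lo, hi):
        m, s = clipped_normal_moments(mu, sd, lo, hi)
        x = np.clip(np.random.default_rng(1).normal(mu, sd, 500_000), lo, hi)
        assert m == pytest.approx(x.mean(), abs=4 * sd / np.sqrt(500_000))
        assert s == pytest.approx(x.std(), abs=4 * sd / np.sqrt(2 * 500_000))


class TestSampleClinical:
    N = 30_000  # enough for ~3 SE checks while staying fast

    @pytest.mark.parametrize("label,stats", [(1, POSITIVE_STATS), (0, NEGATIVE_STATS)])
    def test_moment_recovery(self, label, stats):
        """Sample moments of every continuous input feature match the target
        class-conditional statistics within 3 standard errors.

        The negative-class age SD is excluded: the printed value exceeds the
        largest SD attainable on the plausible-age support, so only its mean
        is targeted.
        """
        rng = np.random.default_rng(42)
        df = records_to_frame(sample_clinical(label, self.N, rng))
        diff = df.nihss_discharge - df.nihss_admission
        checks = [
            (df.age.mean(), stats.age_mean, stats.age_sd / np.sqrt(self.N)),
            (df.lohs.mean(), stats.lohs_mean, stats.lohs_sd / np.sqrt(self.N)),
            (df.lohs.std(), stats.lohs_sd, stats.lohs_sd / np.sqrt(2 * self.N)),
            (df.nihss_admission.mean(), stats.nihss_adm_mean,
             stats.nihss_adm_sd / np.sqrt(self.N)),
            (df.nihss_admission.std(), stats.nihss_adm_sd,
             stats.nihss_adm_sd / np.sqrt(2 * self.N)),
            (df.nihss_discharge.mean(), stats.nihss_dis_mean,
             stats.nihss_dis_sd / np.sqrt(self.N)),
            (df.nihss_discharge.std(), stats.nihss_dis_sd,
             stats.nihss_dis_sd / np.sqrt(2 * self.N)),
            (diff.std(), stats.nihss_diff_sd, stats.nihss_diff_sd / np.sqrt(2 * self.N)),
        ]
        if label == 1:
            checks.append((df.age.std(), stats.age_sd, stats.age_sd / np.sqrt(2 * self.N)))
        for got, want, se in checks:
            assert got == pytest.approx(want, abs=3 * se)

    def test_zero_correlation_diff_sd_is_closed_form(self):
        """With independent admission/discharge scores the change SD is the
        root-sum-square of the marginal SDs."""
        cfg = CohortConfig(nihss_corr_pos=0.0, **SMALL_VOL)
        rng = np.random.default_rng(3)
        df = records_to_frame(sample_clinical(1, 50_000, rng, cfg))
        expected = np.sqrt(2.48 ** 2 + 2.23 ** 2)  # ~3.334
        assert (df.nihss_discharge - df.nihss_admission).std() == pytest.approx(
            expected, abs=0.04)

    def test_labels_always_consistent_with_rule(self):
        rng = np.random.default_rng(4)
        for label in (0, 1):
            for rec in sample_clinical(label, 500, rng):
                assert derive_nd_label(rec.nihss_admission, rec.nihss_max) == label
                assert rec.nihss_max >= rec.nihss_admission

    def test_scores_within_bounds(self):
        rng = np.random.default_rng(5)
        df = records_to_frame(sample_clinical(0, 2000, rng))
        assert (df[["nihss_admission", "nihss_discharge"]].to_numpy() >= 0).all()
        assert (df.lohs > 0).all() and df.age.between(18, 100).all()


class TestRenderVolume:
    def test_same_seed_gives_identical_volumes(self):
        cfg = CohortConfig(**SMALL_VOL)
        v1 = render_volume(1, np.random.default_rng(9), cfg)
        v2 = render_volume(1, np.random.default_rng(9), cfg)
        np.testing.assert_array_equal(v1, v2)

    def test_positive_lesion_brighter_without_noise(self):
        cfg = CohortConfig(noise_sd=0.0, **SMALL_VOL)
        vp = render_volume(1, np.random.default_rng(1), cfg)
        vn = render_volume(0, np.random.default_rng(1), cfg)
        assert vp.max() > vn.max()

    def test_lesion_voxel_count_matches_analytic_sphere(self):
        """Voxels above the background level form a sphere whose count lies
        within a tolerant band around 4/3 pi r^3 (discretization slack)."""
        cfg = CohortConfig(noise_sd=0.0, volume_shape=(16, 32, 32),
                           lesion_radius_range=(2.0, 4.0))
        r_min, r_max = cfg.lesion_radius_range
        vol = render_volume(1, np.random.default_rng(2), cfg)
        count = int((vol > 1.5).sum())  # background is 1 inside the phantom
        lo = 4 / 3 * np.pi * r_min ** 3 * 0.5
        hi = 4 / 3 * np.pi * r_max ** 3 * 1.5
        assert lo <= count <= hi

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(volume_shape=(4, 8, 8), lesion_radius_range=(3.0, 5.0))

    def test_normalization_zero_mean_unit_sd_in_foreground(self):
        cfg = CohortConfig(**SMALL_VOL)
        v = normalize_volume(render_volume(0, np.random.default_rng(3), cfg))
        fg = v[v != 0]
        assert abs(fg.mean()) < 1e-9 and fg.std() == pytest.approx(1.0, abs=1e-9)


class TestStandardizeTabular:
    def _records(self, n=6, seed=0):
        return sample_clinical(0, n, np.random.default_rng(seed))

    def test_record_at_train_mean_maps_to_zero(self):
        recs = self._records()
        stats = train_feature_stats(recs)
        rec = dataclasses.replace(
            recs[0], lohs=stats["lohs"][0], nihss_admission=stats["nihss_admission"][0],
            nihss_discharge=stats["nihss_discharge"][0])
        row = standardize_tabular([rec], stats)[0]
        np.testing.assert_allclose(row[:3], 0.0, atol=1e-12)

    def test_binary_stenosis_passes_through(self):
        recs = self._records(12, seed=3)
        stats = train_feature_stats(recs)
        x = standardize_tabular(recs, stats)
        np.testing.assert_array_equal(x[:, 3], tabular_matrix(recs)[:, 3])
        assert set(np.unique(x[:, 3])) <= {0.0, 1.0}

    def test_self_standardization_gives_unit_moments(self):
        recs = self._records(50, seed=4)
        x = standardize_tabular(recs, train_feature_stats(recs))
        np.testing.assert_allclose(x[:, :3].mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(x[:, :3].std(axis=0), 1.0, atol=1e-10)

    def test_zero_sd_feature_rejected(self):
        recs = self._records(4)
        stats = train_feature_stats(recs)
        stats["lohs"] = (stats["lohs"][0], 0.0)
        with pytest.raises(ValueError, match="zero training SD"):
            standardize_tabular(recs, stats)


class TestGenerateCohort:
    def test_class_counts_and_label_consistency(self):
        cfg = CohortConfig(n_total=30, n_positive=10, seed=1, **SMALL_VOL)
        records, volumes, labels = generate_cohort(cfg)
        assert len(records) == 30 and labels.sum() == 10
        assert volumes.shape == (30, 8, 16, 16)
        for rec in records:
            assert rec.nd_label == derive_nd_label(rec.nihss_admission, rec.nihss_max)

    def test_two_sample_cohort(self):
        cfg = CohortConfig(n_total=2, n_positive=1, seed=2, **SMALL_VOL)
        _, _, labels = generate_cohort(cfg)
        assert sorted(labels) == [0, 1]

    def test_identical_seeds_identical_cohorts(self):
        cfg = CohortConfig(n_total=10, n_positive=4, seed=11, **SMALL_VOL)
        r1, v1, l1 = generate_cohort(cfg)
        r2, v2, l2 = generate_cohort(cfg)
        assert records_to_frame(r1).equals(records_to_frame(r2))
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(l1, l2)

    def test_exact_binary_counts_scale_with_n(self):
        # at half the class sizes, counts are the rounded halves
        cfg = CohortConfig(n_total=193, n_positive=63, seed=3,
                           exact_count_binaries=True, **SMALL_VOL)
        records, _, labels = generate_cohort(cfg, include_volumes=False)
        df = records_to_frame(records)
        pos = df[df.nd_label == 1]
        assert pos.vas.sum() == round(31 * 63 / 126)
        assert pos.thrombolysis.sum() == round(14 * 63 / 126)
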