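"""Synthetic scene generator: layouts, stacks, samples, recovery."""

import numpy as np
import pandas as pd
import pytest

import marshphen as mp
from marshphen.errors import ConfigError, SampleShortageError
from marshphen.features import extract_phenology_rasters, pixel_monthly_features


class TestClassMap:
    def test_block_layout_equal_partition(self):
        cfg = mp.SceneConfig(grid_shape=(20, 20), seed=1)
        labels = mp.generate_class_map(cfg)
        counts = np.bincount(labels.ravel())[1:5]
        np.testing.assert_array_equal(counts, [100, 100, 100, 100])

    def test_pigeonhole_2x2(self):
        cfg = mp.SceneConfig(grid_shape=(2, 2), seed=1)
        labels = mp.generate_class_map(cfg)
        assert sorted(labels.ravel()) == [1, 2, 3, 4]

    def test_deterministic_given_seed(self):
        cfg = mp.SceneConfig(grid_shape=(9, 7), class_layout="random", seed=5)
        np.testing.assert_array_equal(mp.generate_class_map(cfg), mp.generate_class_map(cfg))

    def test_random_layout_covers_all_classes(self):
        cfg = mp.SceneConfig(grid_shape=(3, 3), class_layout="random", seed=2)
        labels = mp.generate_class_map(cfg)
        assert set(np.unique(labels)) == {1, 2, 3, 4}

    def test_zero_area_grid_rejected(self):
        with pytest.raises(ConfigError):
            mp.SceneConfig(grid_shape=(0, 5))


class TestOpticalStack:
    def test_noiseless_observations_on_curve(self, clean_scene):
        optical, labels = clean_scene["optical"], clean_scene["labels"]
        profiles = clean_scene["pheno_profiles"]
        assert optical.valid.all()
        ndvi = optical.ndvi()
        for short, profile in profiles.items():
            m = labels == mp.CLASS_CODES[short]
            expected = profile.ndvi_curve(optical.dates)
            np.testing.assert_allclose(
                ndvi[:, m], np.tile(expected[:, None], (1, int(m.sum()))), atol=1e-12
            )

    def test_curve_attains_configured_extrema(self):
        profile = mp.default_pheno_profiles(noise_sd=0.0)["TC"]
        curve = profile.ndvi_curve(np.arange(1.0, 366.0))
        assert curve.max() == pytest.approx(profile.mv, abs=1e-12)
        assert curve.min() == pytest.approx(profile.bv, abs=1e-12)

    def test_flooded_band_trips_filter(self):
        cfg = mp.SceneConfig(grid_shape=(4, 6), cloud_prob=0.0, seed=3)
        tide = mp.TideModel(shore_prob=1.0, inland_prob=0.0, shore_cols=2)
        profiles = mp.default_pheno_profiles(noise_sd=0.0)
        labels = mp.generate_class_map(cfg)
        optical = mp.generate_optical_stack(cfg, profiles, tide, labels)
        mndwi = optical.mndwi()
        assert np.all(mndwi[:, :, 4:] > -0.1)   # shoreline band always flooded
        assert np.all(mndwi[:, :, :4] < -0.1)
        result = extract_phenology_rasters(optical)
        assert result.excluded[:, 4:].all()
        assert not result.excluded[:, :4].any()

    def test_missing_profile_rejected(self, clean_scene):
        profiles = dict(clean_scene["pheno_profiles"])
        del profiles["SS"]
        with pytest.raises(ConfigError):
            mp.generate_optical_stack(
                clean_scene["config"], profiles, clean_scene["tide"], clean_scene["labels"]
            )

    def test_deterministic_given_seed(self):
        cfg = mp.SceneConfig(grid_shape=(5, 5), seed=9)
        profiles = mp.default_pheno_profiles()
        tide = mp.TideModel()
        labels = mp.generate_class_map(cfg)
        a = mp.generate_optical_stack(cfg, profiles, tide, labels)
        b = mp.generate_optical_stack(cfg, profiles, tide, labels)
        np.testing.assert_array_equal(a.nir, b.nir)
        np.testing.assert_array_equal(a.valid, b.valid)


class TestSarStack:
    def test_noiseless_monthly_features_equal_profile(self, clean_scene):
        """Monthly aggregation of a noiseless stack reproduces the tables."""
        sar, labels = clean_scene["sar"], clean_scene["labels"]
        profiles = clean_scene["sar_profiles"]
        for short, profile in profiles.items():
            r, c = [int(v[0]) for v in np.nonzero(labels == mp.CLASS_CODES[short])]
            feats = pixel_monthly_features(sar, r, c)
            expected_diff = np.asarray(profile.monthly_vv_db) - np.asarray(profile.monthly_vh_db)
            np.testing.assert_allclose(feats.diff_by_month, expected_diff, atol=1e-9)

    def test_june_difference_is_class_maximum_for_tc(self, clean_scene):
        sar, labels = clean_scene["sar"], clean_scene["labels"]
        r, c = [int(v[0]) for v in np.nonzero(labels == mp.CLASS_CODES["TC"])]
        feats = pixel_monthly_features(sar, r, c)
        assert int(np.argmax(feats.diff_by_month)) == 5

    def test_identical_profiles_identical_features(self):
        cfg = mp.SceneConfig(grid_shape=(2, 2), classes=("PA", "SS"), seed=4)
        base = mp.default_sar_profiles(noise_sd_db=0.0)["PA"]
        profiles = {
            "PA": base,
            "SS": mp.ClassSarProfile("SS", base.monthly_vv_db, base.monthly_vh_db, 0.0),
        }
        labels = mp.generate_class_map(cfg)
        sar = mp.generate_sar_stack(cfg, profiles, labels)
        np.testing.assert_allclose(sar.vv_db[:, 0, 0], sar.vv_db[:, -1, -1])

    def test_sar_date_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            mp.SceneConfig(sar_dates=(10, 400))


class TestSamples:
    def test_stratified_counts(self, clean_scene):
        samples = mp.generate_samples(clean_scene["labels"], 3, seed=0)
        assert len(samples) == 12
        assert samples.groupby("class_code").size().eq(3).all()

    def test_zero_request_empty_table(self, clean_scene):
        assert len(mp.generate_samples(clean_scene["labels"], 0, seed=0)) == 0

    def test_shortage_error(self, clean_scene):
        with pytest.raises(SampleShortageError):
            mp.generate_samples(clean_scene["labels"], 5, seed=0)  # only 4 px/class

    def test_deterministic_and_without_replacement(self):
        cfg = mp.SceneConfig(grid_shape=(10, 10), seed=8)
        labels = mp.generate_class_map(cfg)
        a = mp.generate_samples(labels, 10, seed=8)
        b = mp.generate_samples(labels, 10, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.duplicated(["row", "col"]).any()


def test_noiseless_pipeline_recovers_configured_phenology(clean_scene):
    """Filter + fit + extraction returns each class's configured
    (sos, eos, bv, mv) within (±3 d, ±3 d, ±0.01, ±0.01)."""
    result = extract_phenology_rasters(clean_scene["optical"])
    labels = clean_scene["labels"]
    for short, profile in clean_scene["pheno_profiles"].items():
        m = labels == mp.CLASS_CODES[short]
        sos, eos, mv, bv, _, _ = result.stack[:, m][:, 0]
        assert sos == pytest.approx(profile.sos_day, abs=3.0), short
        assert eos == pytest.approx(profile.eos_day, abs=3.0), short
        assert mv == pytest.approx(profile.mv, abs=0.01), short
        assert bv == pytest.approx(profile.bv, abs=0.01), short
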