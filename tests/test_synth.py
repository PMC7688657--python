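import math

import numpy as np
import pandas as pd
import pytest

from stedpuncta.config import InvalidConfigError, PipelineConfig
from stedpuncta.synth import (
    GroundTruth,
    SynthConfig,
    expected_gaussian_ratio,
    expected_gradient_ratios,
    make_spread_gradient_fixture,
    render_field,
    render_synapse_crop,
    sample_synapse_population,
    simulate_dataset,
)


class TestSynthConfig:
    def test_invalid_counts(self):
        with pytest.raises(InvalidConfigError):
            SynthConfig(n_synapses=0)
        with pytest.raises(InvalidConfigError):
            SynthConfig(n_experiments=0)

    def test_undersampled_psf_warns_but_allowed(self):
        with pytest.warns(UserWarning, match="undersampled"):
            SynthConfig(psf_fwhm_nm={"poi": 10.0, "post_marker": 60.0,
                                     "pre_marker": 60.0, "actin": 250.0})

    def test_psf_sigma_conversion(self):
        cfg = SynthConfig()
        assert cfg.psf_sigma_px("poi") == pytest.approx(
            60.0 / (2 * math.sqrt(2 * math.log(2))) / 30.0
        )


class TestSamplePopulation:
    def test_zero_rate_gives_zero_spots(self):
        cfg = SynthConfig(poi_spot_rate=0.0, n_synapses=50, seed=1)
        truth = sample_synapse_population(cfg)
        assert (truth.synapses["poi_spot_count"] == 0).all()
        assert truth.spots.empty

    def test_pre_post_amplitudes_uncorrelated(self):
        """S and A are independent, so rendered post- and pre-synaptic
        amplitudes decorrelate (|r| < 0.2 at n = 200); r recomputed by the
        direct product-moment formula."""
        cfg = SynthConfig(n_synapses=200, seed=7, batch_sd_log=1e-9)
        t = sample_synapse_population(cfg).synapses
        x, y = t["homer_amp"].to_numpy(), t["pre_amp"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        assert abs(r) < 0.2

    def test_constant_spread_recovered(self):
        """With spread coupling 0, the sampled radial offsets have per-axis
        sd equal to the configured sigma within 3 standard errors."""
        cfg = SynthConfig(n_synapses=300, poi_spread_coupling=0.0,
                          poi_spread_nm=250.0, seed=3)
        truth = sample_synapse_population(cfg)
        merged = truth.spots.merge(
            truth.synapses[["synapse_id", "row", "col"]], on="synapse_id"
        )
        offsets = np.concatenate([
            merged["row_x"] - merged["row_y"],
            merged["col_x"] - merged["col_y"],
        ])
        sigma_px = 250.0 / 30.0
        se = sigma_px / math.sqrt(2 * (len(offsets) - 1))
        assert np.std(offsets, ddof=1) == pytest.approx(sigma_px, abs=3 * se)

    def test_spots_inside_bounds(self):
        cfg = SynthConfig(n_synapses=100, poi_spread_nm=900.0, seed=5)
        truth = sample_synapse_population(cfg)
        h, w = cfg.image_size_px
        assert truth.spots["row"].between(0, h - 1).all()
        assert truth.spots["col"].between(0, w - 1).all()

    def test_homer_moment_recovery(self):
        """Sampled homer amplitude mean matches the log-normal target
        within 3 standard errors at n >= 200."""
        cfg = SynthConfig(n_synapses=400, seed=9, batch_sd_log=1e-9)
        t = sample_synapse_population(cfg).synapses
        target_mean = cfg.homer_amp * math.exp(
            (cfg.s_sigma_log**2 + cfg.amp_noise_sd_log**2) / 2
        )
        x = t["homer_amp"].to_numpy()
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert x.mean() == pytest.approx(target_mean, abs=3 * se)

    def test_monotone_spread_design(self):
        """Positive spread coupling: rank correlation between the latent and
        the true spot spread is exactly 1 before noise."""
        from scipy.stats import spearmanr

        cfg = SynthConfig(n_synapses=100, poi_spread_coupling=0.5, seed=2)
        t = sample_synapse_population(cfg).synapses
        rho = spearmanr(t["A"], t["poi_spread_nm"]).statistic
        assert rho == pytest.approx(1.0)

    def test_determinism(self):
        cfg = SynthConfig(n_synapses=40, seed=11)
        a = sample_synapse_population(cfg)
        b = sample_synapse_population(cfg)
        pd.testing.assert_frame_equal(a.synapses, b.synapses)
        pd.testing.assert_frame_equal(a.spots, b.spots)


class TestRenderField:
    def test_zero_everything_gives_zero_channel(self):
        cfg = SynthConfig(n_synapses=4, poi_spot_rate=0.0, background=0.0,
                          seed=1)
        truth = sample_synapse_population(cfg)
        fid = truth.synapses["field_id"].iloc[0]
        img = render_field(truth, cfg, fid, noise=False)
        assert np.all(img["poi"] == 0.0)

    def test_single_point_integral_matches_amplitude(self):
        """A unit-amplitude point with no noise integrates to 1 within 1 %
        (discretized PSF is normalized)."""
        cfg = SynthConfig(n_synapses=1, poi_spot_rate=0.0, background=0.0,
                          homer_amp=1.0, amp_noise_sd_log=1e-12,
                          batch_sd_log=1e-12, s_sigma_log=1e-12, seed=4)
        truth = sample_synapse_population(cfg)
        fid = truth.synapses["field_id"].iloc[0]
        img = render_field(truth, cfg, fid, noise=False)
        assert img["post_marker"].sum() == pytest.approx(1.0, rel=0.01)

    def test_bit_identical_rerun(self):
        cfg = SynthConfig(n_synapses=20, seed=13)
        imgs1, t1 = simulate_dataset(cfg)
        imgs2, t2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(t1.synapses, t2.synapses)
        for a, b in zip(imgs1, imgs2):
            for role in a.channels:
                np.testing.assert_array_equal(a[role], b[role])

    def test_unknown_field_rejected(self):
        cfg = SynthConfig(n_synapses=4, seed=1)
        truth = sample_synapse_population(cfg)
        with pytest.raises(ValueError):
            render_field(truth, cfg, "nope")

    def test_missing_psf_role_rejected(self):
        cfg = SynthConfig(n_synapses=4, seed=1)
        truth = sample_synapse_population(cfg)
        cfg2 = SynthConfig(n_synapses=4, seed=1,
                           psf_fwhm_nm={"poi": 60.0, "post_marker": 60.0,
                                        "pre_marker": 60.0, "actin": 250.0})
        del cfg2.psf_fwhm_nm["actin"]
        fid = truth.synapses["field_id"].iloc[0]
        with pytest.raises(InvalidConfigError, match="actin"):
            render_field(truth, cfg2, fid)


class TestSpreadGradientFixture:
    def test_non_increasing_sigma_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_spread_gradient_fixture(5, [200.0, 200.0, 300.0, 400.0, 500.0])

    def test_zero_crops_warns(self):
        with pytest.warns(UserWarning):
            crops, truth = make_spread_gradient_fixture(
                0, [100.0, 200.0, 300.0, 400.0, 500.0]
            )
        assert crops == []
        assert truth.synapses.empty

    def test_bin_labels_and_counts(self, scfg, pcfg):
        crops, truth = make_spread_gradient_fixture(
            3, [100.0, 200.0, 300.0], scfg, pcfg, noise=False
        )
        assert len(crops) == 9
        assert truth.synapses["bin_true"].tolist() == [1] * 3 + [2] * 3 + [3] * 3
        # marker amplitude increases with bin
        means = truth.synapses.groupby("bin_true")["homer_amp"].mean()
        assert means.is_monotonic_increasing

    def test_degenerate_equal_sigma_no_trend(self, scfg, pcfg):
        """All-equal spreads (strictness off): the bin-5 minus bin-1 ratio
        difference is statistically indistinguishable from zero."""
        from stedpuncta.pipeline import run_crops

        crops, _ = make_spread_gradient_fixture(
            100, [300.0] * 5, scfg, pcfg, noise=True, strict=False,
            rng=np.random.default_rng(21),
        )
        res = run_crops(crops, pcfg, marker_role="post_marker",
                        detect_spot_sets=False)
        assert abs(res.ratio_delta) < 0.05


class TestAnalyticRatios:
    def test_wide_limit_approaches_one(self):
        assert expected_gaussian_ratio(1e6) == pytest.approx(1.0, abs=1e-6)

    def test_background_pulls_ratio_towards_one(self):
        tight = expected_gaussian_ratio(8.0)
        with_bg = expected_gaussian_ratio(8.0, peak=1.0, background=0.5)
        assert tight < with_bg < 1.0

    def test_gradient_ratios_increase(self, scfg, pcfg):
        ratios = expected_gradient_ratios(
            (150.0, 250.0, 350.0, 450.0, 550.0), scfg, pcfg
        )
        assert all(b > a for a, b in zip(ratios, ratios[1:]))


def test_render_synapse_crop_centres_punctum(scfg, pcfg):
    crop = render_synapse_crop(scfg, pcfg.side_px, 1000.0, 500.0, [], [],
                               rng=None)
    post = crop.channels["post_marker"]
    assert post[50, 50] == post.max()
    assert crop.mean_intensity["post_marker"] > scfg.background
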