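import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from stedpuncta.stats import (
    bin_summary,
    correlate,
    linear_fit,
    significance_stars,
    spearman,
)


def brute_force_rho(x, y):
    """Independent oracle: Pearson correlation of explicitly computed
    average ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean(); ry -= ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_worked_five_point_example(self):
        # d^2 = (0,1,1,0,... ) sums to 4: rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_on_all_permutations(self, n):
        x = list(range(1, n + 1))
        for perm in itertools.permutations(x):
            rho, _ = spearman(x, list(perm))
            assert rho == pytest.approx(brute_force_rho(x, perm), abs=1e-12)

    def test_ties_match_scipy(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_small_n(self):
        """For n <= 9 the p-value is the exact permutation tail; cross-check
        against scipy's exhaustive permutation test."""
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        _, p = spearman(x, y)

        def stat(yy):
            return sps.spearmanr(x, yy).statistic

        ref = sps.permutation_test(
            (y,), stat, permutation_type="pairings", n_resamples=np.inf,
            alternative="two-sided",
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_input_flagged(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)

    def test_large_n_t_approximation(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(scale=2.0, size=200)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [2.0, 1.0])


class TestBinSummary:
    def test_two_value_bin(self):
        out = bin_summary([3.0, 5.0], [1, 1])
        assert out.loc[0, "mean"] == 4.0
        assert out.loc[0, "sem"] == pytest.approx(1.0)  # sd sqrt(2)/sqrt(2)

    def test_singleton_bin_sem_missing(self):
        out = bin_summary([7.0], [1])
        assert out.loc[0, "mean"] == 7.0
        assert math.isnan(out.loc[0, "sem"])

    def test_within_bin_order_invariance(self, rng):
        v = rng.uniform(0, 1, size=20)
        bins = np.repeat([1, 2], 10)
        perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(10)])
        a = bin_summary(v, bins)
        b = bin_summary(v[perm], bins[perm])
        np.testing.assert_allclose(a["mean"], b["mean"])
        np.testing.assert_allclose(a["sem"], b["sem"])


class TestLinearFit:
    def test_exact_line(self):
        slope, intercept = linear_fit([0.0, 1.0, 2.0, 3.0], [1.0, 3.0, 5.0, 7.0])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_two_points_interpolate(self):
        slope, intercept = linear_fit([1.0, 3.0], [5.0, 9.0])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)

    def test_symmetric_noise_about_flat_line(self):
        # closed-form OLS on a fixed antisymmetric fixture: slope exactly 0
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([5.0 + 0.3, 5.0 - 0.2, 5.0, 5.0 - 0.3, 5.0 + 0.2])
        slope, intercept = linear_fit(x, y)
        sx = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert slope == pytest.approx(sx)
        assert abs(slope) < 0.05

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_slope_recovery_on_noisy_linear_data(self, rng):
        """With POI abundance a * marker + noise, the fitted slope recovers
        a within 3 standard errors (n = 500)."""
        a = 0.75
        marker = rng.lognormal(0, 0.5, size=500)
        poi = a * marker + rng.normal(0, 0.3, size=500)
        slope, _ = linear_fit(marker, poi)
        # standard error of the OLS slope
        resid = poi - (slope * marker + (poi - slope * marker).mean())
        se = math.sqrt(
            (resid @ resid) / 498 / ((marker - marker.mean()) @ (marker - marker.mean()))
        )
        assert abs(slope - a) < 3 * se


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.049, "*"),
            (0.05, "ns."),
            (0.5, "ns."),
            (0.009, "**"),
            (0.01, "*"),
            (0.0009, "***"),
            (1e-6, "****"),
            (0.0, "****"),
            (1.0, "ns."),
        ],
    )
    def test_thresholds_strict(self, p, label):
        assert significance_stars(p) == label

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_out_of_range(self, p):
        with pytest.raises(ValueError):
            significance_stars(p)


def test_correlate_bundles_consistent_pieces(rng):
    marker = rng.lognormal(0, 0.5, size=100)
    poi = 0.5 * marker + rng.normal(0, 0.2, size=100)
    bins = np.ones(100, dtype=int)
    bins[marker > np.median(marker)] = 2
    res = correlate(poi, marker, bins, marker="post_marker", poi="calreticulin")
    rho, p = spearman(marker, poi)
    assert res.spearman_rho == rho
    assert res.p_value == p
    assert res.n == 100
    assert res.stars == significance_stars(p)
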