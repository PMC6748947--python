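import numpy as np
import pandas as pd
import pytest

from loopfit.background import (
    BackgroundModel,
    enumerate_pairs,
    equal_occupancy_binning,
    fit_background,
    fit_bias_regression,
    fit_coefficient_splines,
    fit_distance_spline,
)
from loopfit.bias import coverage_bias, unit_bias
from loopfit.io_contacts import BinAnnotation, BinnedContactMap


def _pairs_frame(distances, counts):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "i": np.arange(len(distances)),
            "j": np.arange(len(distances)) + 1,
            "distance": distances,
            "count": counts,
        }
    ).sort_values("distance").reset_index(drop=True)


class TestEnumeratePairs:
    def _ann(self, flags):
        ann = BinAnnotation(binsize=5000, n_bins={"chr1": len(flags)})
        ann.peak_flags["chr1"] = np.asarray(flags, dtype=bool)
        return ann

    def test_one_peak_bin(self):
        # bins 0..2 all mutually in range with distance window 5-10 kb
        ann = self._ann([True, False, False])
        cmap = BinnedContactMap(binsize=5000)
        pairs = enumerate_pairs(cmap, ann, "L", 5000, 10_000)
        assert len(pairs) == 2  # (0,1) and (0,2)
        with pytest.raises(ValueError):
            enumerate_pairs(cmap, ann, "S", 5000, 10_000)

    def test_three_peak_bins_stringent(self):
        ann = self._ann([True, True, True])
        cmap = BinnedContactMap(binsize=5000)
        pairs = enumerate_pairs(cmap, ann, "S", 5000, 10_000)
        assert len(pairs) == 3  # C(3,2)

    def test_distance_range_excludes(self):
        ann = self._ann([True, True, True, True, True])
        cmap = BinnedContactMap(binsize=5000)
        cmap.add("chr1", 0, 1, 5)  # d = 5 kb, below range
        pairs = enumerate_pairs(cmap, ann, "S", 10_000, 20_000)
        assert (pairs["distance"] >= 10_000).all()
        assert (0, 1) not in set(zip(pairs["i"], pairs["j"]))

    def test_zero_count_pairs_included(self):
        ann = self._ann([True, True, True])
        cmap = BinnedContactMap(binsize=5000)
        cmap.add("chr1", 0, 1, 7)
        pairs = enumerate_pairs(cmap, ann, "S", 5000, 10_000)
        counts = dict(zip(zip(pairs["i"], pairs["j"]), pairs["count"]))
        assert counts[(0, 1)] == 7
        assert counts[(1, 2)] == 0


class TestEqualOccupancyBinning:
    def test_exact_divisibility(self):
        # 100 pairs at distinct distances, 1 contact each: C=100, M=10
        pairs = _pairs_frame(np.arange(100) * 1000 + 20_000, np.ones(100, dtype=int))
        bins = equal_occupancy_binning(pairs, M=10)
        assert len(bins) == 10
        assert all(b.total_count == 10 for b in bins)

    def test_prior_probability_formula(self):
        # a bin with S_j=10, n_j=5, C=100 -> p_j = (10/5)/100 = 0.02
        counts = np.zeros(50, dtype=int)
        counts[:5] = 2  # first distance-sorted 5 pairs carry S=10
        counts[5:] = 2
        pairs = _pairs_frame(np.arange(50) * 1000 + 20_000, counts)
        bins = equal_occupancy_binning(pairs, M=10)
        b0 = bins[0]
        assert b0.total_count == 10 and b0.n_pairs == 5
        assert b0.prior_probability == pytest.approx((10 / 5) / 100)

    def test_tie_rule_single_bin(self):
        pairs = _pairs_frame(np.full(30, 40_000), np.arange(30))
        bins = equal_occupancy_binning(pairs, M=5)
        assert len(bins) == 1
        assert bins[0].total_count == pairs["count"].sum()

    def test_conservation_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(20, 400))
            pairs = _pairs_frame(
                rng.integers(4, 400, size=n) * 5000, rng.poisson(3, size=n)
            )
            if pairs["count"].sum() == 0:
                continue
            M = int(rng.integers(2, 50))
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    bins = equal_occupancy_binning(pairs, M=M)
            assert sum(b.n_pairs for b in bins) == len(pairs)
            assert sum(b.total_count for b in bins) == pairs["count"].sum()
            assert len(bins) <= M

    def test_c_less_than_m_reduces(self):
        pairs = _pairs_frame(np.arange(5) * 5000 + 20_000, np.ones(5, dtype=int))
        with pytest.warns(UserWarning, match="reducing M"):
            bins = equal_occupancy_binning(pairs, M=50)
        assert len(bins) == 5

    def test_zero_total_rejected(self):
        pairs = _pairs_frame(np.arange(5) * 5000 + 20_000, np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            equal_occupancy_binning(pairs, M=2)


def _isotonic_oracle(d, p):
    """Pool-adjacent-violators for a non-increasing fit (brute force)."""
    blocks = [[v] for v in p]
    weights = [1] * len(p)
    means = [float(v) for v in p]
    changed = True
    while changed:
        changed = False
        for t in range(len(means) - 1):
            if means[t] < means[t + 1] - 1e-15:
                merged = blocks[t] + blocks[t + 1]
                blocks[t : t + 2] = [merged]
                means[t : t + 2] = [float(np.mean(merged))]
                weights[t : t + 2] = [len(merged)]
                changed = True
                break
    out = []
    for blk, mu in zip(blocks, means):
        out.extend([mu] * len(blk))
    return np.array(out)


class TestDistanceSpline:
    def test_decreasing_data_preserved(self):
        d = np.linspace(20_000, 2_000_000, 30)
        p = 1e-3 / (d / 20_000)
        f = fit_distance_spline(d, p)
        assert f(d[0]) >= f(d[-1])
        grid = np.linspace(d[0], d[-1], 1000)
        vals = f(grid)
        assert np.max(np.abs(p - f(d))) <= 0.1 * p.max()
        assert (np.diff(vals) <= 1e-12).all()

    def test_constant_input(self):
        d = np.linspace(20_000, 100_000, 10)
        f = fit_distance_spline(d, np.full(10, 0.5))
        np.testing.assert_allclose(f(np.linspace(20_000, 100_000, 50)), 0.5, atol=1e-9)

    def test_noisy_blip_still_monotone_and_tracks_isotonic(self):
        rng = np.random.default_rng(7)
        d = np.linspace(20_000, 500_000, 25)
        p = 1e-3 * np.exp(-d / 200_000)
        p[10] *= 1.8  # upward blip
        iso = _isotonic_oracle(d, p)
        f = fit_distance_spline(d, p)
        grid = np.linspace(d[0], d[-1], 1000)
        vals = f(grid)
        assert (np.diff(vals) <= 1e-12).all()
        # spline tracks the isotonic projection at the knots
        assert np.max(np.abs(f(d) - iso)) <= 0.1 * p.max()

    def test_clamped_outside_domain(self):
        d = np.linspace(20_000, 100_000, 10)
        p = np.linspace(1e-3, 1e-4, 10)
        f = fit_distance_spline(d, p)
        assert f(5_000) == pytest.approx(f(20_000))
        assert f(10**7) == pytest.approx(f(100_000))

    def test_few_points_fallback(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            f = fit_distance_spline([20_000, 40_000, 60_000], [3e-3, 2e-3, 1e-3])
        assert f(30_000) == pytest.approx(2.5e-3)

    def test_nonnegative(self):
        d = np.linspace(20_000, 100_000, 10)
        p = np.linspace(1e-3, 0.0, 10)
        f = fit_distance_spline(d, p)
        assert (f(np.linspace(20_000, 100_000, 200)) >= 0).all()


def _ols_oracle(y, X):
    """Closed-form OLS via normal equations."""
    XtX = X.T @ X
    return np.linalg.solve(XtX, X.T @ y)


class TestBiasRegression:
    def test_log_linear_recovery(self):
        rng = np.random.default_rng(0)
        b1 = rng.lognormal(0, 0.5, 300)
        b2 = rng.lognormal(0, 0.5, 300)
        k = np.maximum(np.round(10 * b1 * b2), 1)
        beta0, beta1, beta2, degen = fit_bias_regression(k, b1, b2)
        # independent closed-form oracle on the same transformed data
        X = np.column_stack([np.ones(300), np.log(b1), np.log(b2)])
        oracle = _ols_oracle(np.log(k), X)
        np.testing.assert_allclose([beta0, beta1, beta2], oracle, rtol=1e-8)
        assert abs(beta0 - np.log(10)) < 0.05
        assert abs(beta1 - 1) < 0.05 and abs(beta2 - 1) < 0.05
        assert not degen

    def test_independent_counts_give_zero_slopes(self):
        rng = np.random.default_rng(1)
        b1 = rng.lognormal(0, 0.5, 2000)
        b2 = rng.lognormal(0, 0.5, 2000)
        k = rng.integers(5, 15, 2000)
        beta0, beta1, beta2, _ = fit_bias_regression(k, b1, b2)
        assert abs(beta1) < 0.1 and abs(beta2) < 0.1

    def test_degenerate_constant_bias(self):
        b1 = np.array([1.0, 2.0, 4.0])
        b2 = np.ones(3)
        k = np.array([2, 4, 8])
        beta0, beta1, beta2, degen = fit_bias_regression(k, b1, b2)
        assert degen
        assert beta2 == 0.0
        assert beta1 == pytest.approx(1.0, abs=1e-8)

    def test_all_biases_equal(self):
        k = np.array([3, 5, 7, 9])
        beta0, beta1, beta2, degen = fit_bias_regression(k, np.ones(4), np.ones(4))
        assert degen and beta1 == 0 and beta2 == 0
        assert beta0 == pytest.approx(np.mean(np.log(k)))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_bias_regression([0, 1, 2], [1, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError):
            fit_bias_regression([1, 2], [1, 1], [1, 1])


class TestCoefficientSplines:
    def test_constant_sequence(self):
        d = np.linspace(20_000, 1_000_000, 20)
        f0, f1, f2 = fit_coefficient_splines(d, np.full(20, 2.0), np.full(20, 1.0), np.full(20, 0.5))
        grid = np.linspace(d[0], d[-1], 100)
        np.testing.assert_allclose(f0(grid), 2.0, atol=1e-6)
        np.testing.assert_allclose(f1(grid), 1.0, atol=1e-6)
        np.testing.assert_allclose(f2(grid), 0.5, atol=1e-6)

    def test_linear_sequence_reproduced_at_knots(self):
        d = np.linspace(20_000, 1_000_000, 20)
        beta = 2.0 - d / 1e6
        f0, _, _ = fit_coefficient_splines(d, beta, beta, beta)
        np.testing.assert_allclose(f0(d), beta, atol=1e-6)

    def test_too_many_missing_aborts(self):
        d = np.linspace(20_000, 1_000_000, 10)
        beta = np.full(10, np.nan)
        beta[:4] = 1.0
        with pytest.raises(ValueError, match="strata"):
            fit_coefficient_splines(d, beta, beta, beta)


class TestFitBackground:
    def test_log_linear_map_recovers_unit_slopes(self, small_fixture):
        fx = small_fixture
        bv = coverage_bias(fx.ann)
        model = fit_background(fx.cmap, fx.ann, bv, "L")
        f0, f1, f2 = model.beta_splines
        grid = np.linspace(50_000, 1_500_000, 30)
        assert np.all(np.abs(f1(grid) - 1) < 0.25)
        assert np.all(np.abs(f2(grid) - 1) < 0.25)

    def test_conservation_totals(self, small_fixture):
        fx = small_fixture
        bv = unit_bias(fx.ann)
        model = fit_background(fx.cmap, fx.ann, bv, "L", use_bias_regression=False)
        occ = model.occupancy_frame()
        pairs = enumerate_pairs(fx.cmap, fx.ann, "L", 20_000, 2_000_000)
        assert occ["n_j"].sum() == len(pairs)
        assert occ["S_j"].sum() == pairs["count"].sum() == model.total_observed

    def test_stringency_ordering(self, enriched_fixture):
        fx = enriched_fixture
        bv = coverage_bias(fx.ann)
        mS = fit_background(fx.cmap, fx.ann, bv, "S", use_bias_regression=False)
        mL = fit_background(fx.cmap, fx.ann, bv, "L", use_bias_regression=False)
        lo = max(mS.distance_spline.lo, mL.distance_spline.lo)
        hi = min(mS.distance_spline.hi, mL.distance_spline.hi)
        grid = np.linspace(lo, hi, 200)
        pS = np.array([mS.prior_probability(x) for x in grid])
        pL = np.array([mL.prior_probability(x) for x in grid])
        assert (pS >= pL - 1e-12).all()

    def test_expected_count_plug_in(self):
        model = BackgroundModel(
            background_class="L", M=1, total_observed=10, occupancy_bins=[]
        )
        from loopfit.background import ClampedSpline

        const = lambda v: ClampedSpline(lambda x: np.full_like(np.asarray(x, float), v), 0, 1e9)
        model.beta_splines = (const(np.log(2)), const(1.0), const(1.0))
        assert model.expected_count(50_000, 2.0, 3.0) == pytest.approx(12.0)
        model.beta_splines = (const(np.log(5)), const(0.0), const(0.0))
        assert model.expected_count(50_000, 7.0, 0.1) == pytest.approx(5.0)
        model.beta_splines = (const(1.5), const(2.0), const(3.0))
        assert model.expected_count(50_000, 1.0, 1.0) == pytest.approx(np.exp(1.5))
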