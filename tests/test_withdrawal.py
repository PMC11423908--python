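import math

import numpy as np
import pytest
from scipy import stats

from milkpk import (
    CappingError,
    InsufficientDataError,
    NotEstimableError,
    RunConfig,
    WindowError,
    WithdrawalTimeModel,
    estimate_wt,
    fit_wt_regression,
    select_time_points,
    simulate_study,
    tolerance_factor,
    upper_tolerance_limit,
)
from milkpk.simulate import calibrate_defaults, default_wt_exclusions
from milkpk.withdrawal import WtRegression


def make_regression(slope=-1.0, intercept=0.0, s=0.2, n=20, x_bar=1.0,
                    s_xx=5.0, times=(0.08, 0.5, 1.0, 1.5)):
    return WtRegression(slope=slope, intercept=intercept, s=s, n=n, df=n - 2,
                        x_bar=x_bar, s_xx=s_xx, times_used=tuple(times),
                        n_animals=8)


@pytest.fixture(scope="module")
def noisefree_datasets():
    out = {}
    for dose in (2.0, 4.0):
        cfg = calibrate_defaults(dose, error_cv=0.0, between_subject_cv=0.0)
        out[dose], _ = simulate_study(cfg)
    return out


class TestSelectTimePoints:
    def test_dose4_nine_times_capped_to_seven(self, noisefree_datasets):
        """The 4 mg/kg milk series is quantifiable at nine times (0.08-3 h);
        excluding 0.17 and 0.75 h leaves exactly seven."""
        ds = noisefree_datasets[4.0]
        with pytest.raises(CappingError):
            select_time_points(ds, "milk", 4.0, max_points=7)
        t, y, n_animals = select_time_points(
            ds, "milk", 4.0, max_points=7, excluded_times=(0.17, 0.75)
        )
        assert sorted(set(t)) == [0.08, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0]
        assert n_animals == 8
        assert t.size == 7 * 8 and y.size == t.size

    def test_dose2_seven_times_uncapped(self, noisefree_datasets):
        """The 2 mg/kg milk series has exactly seven quantifiable times
        (0.08-1.5 h); no exclusion is needed."""
        t, _, _ = select_time_points(noisefree_datasets[2.0], "milk", 2.0)
        assert sorted(set(t)) == [0.08, 0.17, 0.25, 0.5, 0.75, 1.0, 1.5]

    def test_fully_censored_is_insufficient(self, noisefree_datasets):
        ds = noisefree_datasets[2.0]
        # exclude every quantifiable time -> nothing left
        with pytest.raises(InsufficientDataError):
            select_time_points(ds, "milk", 2.0, excluded_times=(
                0.08, 0.17, 0.25, 0.5, 0.75, 1.0, 1.5))


class TestFitRegression:
    def test_perfect_line(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = 1.0 - 0.5 * t
        reg = fit_wt_regression(t, y)
        assert reg.slope == pytest.approx(-0.5)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.s == pytest.approx(0.0, abs=1e-12)
        assert reg.df == 2

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(0, 3, 20)
        y = rng.normal(size=20)
        reg = fit_wt_regression(t, y)
        # independent closed-form least squares via the normal equations
        X = np.column_stack([np.ones(20), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.intercept == pytest.approx(beta[0], rel=1e-10)
        assert reg.slope == pytest.approx(beta[1], rel=1e-10)
        sse = np.sum((y - X @ beta) ** 2)
        assert reg.s == pytest.approx(math.sqrt(sse / 18), rel=1e-10)

    def test_duplication_pooling_arithmetic(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.9, 0.6, -0.1, -0.4])
        single = fit_wt_regression(t, y)
        doubled = fit_wt_regression(np.tile(t, 2), np.tile(y, 2))
        assert doubled.slope == pytest.approx(single.slope)
        assert doubled.s_xx == pytest.approx(2 * single.s_xx)
        assert doubled.n == 2 * single.n

    def test_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            fit_wt_regression([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(Exception, match="time-variance"):
            fit_wt_regression([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestToleranceFactor:
    def test_median_median_is_zero(self):
        # p=0.5 makes the noncentrality zero; the central t median is 0
        assert tolerance_factor(20, 18, 0.05, 0.5, 0.5) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_in_leverage(self):
        d = np.linspace(0.02, 2.0, 40)
        k = tolerance_factor(20, 18, d, 0.95, 0.95)
        assert np.all(np.diff(k) > 0)

    def test_coverage_simulation(self):
        """The 95/95 limit exceeds the true 95th percentile of an individual
        observation at x0 in ~95% of replicates (fast 4000-rep check)."""
        rng = np.random.default_rng(12)
        n, sigma, x0 = 20, 0.3, 8.0
        x = np.linspace(0, 6, n)
        a, b = 1.0, -0.7
        reps = 4000
        y = a + b * x + sigma * rng.standard_normal((reps, n))
        x_bar = x.mean()
        s_xx = np.sum((x - x_bar) ** 2)
        slope = (y - y.mean(axis=1, keepdims=True)) @ (x - x_bar) / s_xx
        intercept = y.mean(axis=1) - slope * x_bar
        resid = y - (intercept[:, None] + slope[:, None] * x[None, :])
        s = np.sqrt(np.sum(resid**2, axis=1) / (n - 2))
        d = 1 / n + (x0 - x_bar) ** 2 / s_xx
        k = tolerance_factor(n, n - 2, d, 0.95, 0.95)
        u = intercept + slope * x0 + k * s
        true_q = a + b * x0 + stats.norm.ppf(0.95) * sigma
        cover = np.mean(u >= true_q)
        assert cover == pytest.approx(0.95, abs=0.015)


class TestUpperToleranceLimit:
    def test_zero_residual_sd_gives_the_line(self):
        reg = make_regression(s=0.0)
        for x0 in (0.0, 1.0, 5.0):
            assert upper_tolerance_limit(reg, x0) == pytest.approx(
                reg.intercept + reg.slope * x0
            )

    def test_positive_margin_at_xbar(self):
        reg = make_regression(s=0.3)
        assert upper_tolerance_limit(reg, reg.x_bar) > reg.predict(reg.x_bar)

    def test_brute_force_formula(self):
        reg = make_regression(slope=-0.8, intercept=1.3, s=0.25, n=17,
                              x_bar=0.9, s_xx=3.7)
        for x0 in (0.0, 0.9, 2.5, 6.0):
            d = 1 / reg.n + (x0 - reg.x_bar) ** 2 / reg.s_xx
            k = math.sqrt(d) * stats.nct.ppf(
                0.95, reg.df, stats.norm.ppf(0.95) / math.sqrt(d)
            )
            expect = reg.intercept + reg.slope * x0 + k * reg.s
            assert upper_tolerance_limit(reg, x0) == pytest.approx(expect, rel=1e-12)


class TestEstimateWt:
    @pytest.mark.parametrize("fraction,reported", [
        (2.99, 3.0), (3.87, 4.0), (3.0, 3.0), (0.25, 1.0),
    ])
    def test_round_up_reporting(self, fraction, reported):
        """Fractional estimates are rounded up to the next whole hour;
        whole-hour estimates are reported as-is."""
        # with s=0 the tolerance limit is the fitted line, so the crossing
        # time is (ln(mrl_conc) - intercept)/slope exactly
        slope = -1.0
        intercept = math.log(0.05) + fraction
        reg = make_regression(slope=slope, intercept=intercept, s=0.0)
        res = estimate_wt(reg, mrl=50.0, density=1.0)
        assert res.wt_estimate == pytest.approx(fraction, abs=1e-5)
        assert res.wt_reported == reported

    def test_round_to_milking_interval(self):
        reg = make_regression(slope=-1.0, intercept=math.log(0.05) + 2.99, s=0.0)
        res = estimate_wt(reg, round_to=12.0)
        assert res.wt_reported == 12.0

    def test_grid_scan_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            reg = make_regression(
                slope=-float(rng.uniform(0.5, 2.0)),
                intercept=float(rng.uniform(0.0, 2.0)),
                s=float(rng.uniform(0.05, 0.4)),
                n=int(rng.integers(10, 40)),
                x_bar=float(rng.uniform(0.5, 2.0)),
                s_xx=float(rng.uniform(1.0, 10.0)),
            )
            res = estimate_wt(reg, t_max_search=40.0)
            grid = np.arange(0.0, 40.0, 1e-4)
            above = upper_tolerance_limit(reg, grid) >= math.log(res.mrl_conc)
            wt_grid = grid[np.flatnonzero(above)[-1]] if above.any() else 0.0
            assert res.wt_estimate == pytest.approx(wt_grid, abs=2e-4)

    def test_scaling_monotonicity(self):
        reg = make_regression(s=0.2)
        base = estimate_wt(reg, t_max_search=50.0).wt_estimate
        for c in (1.5, 3.0, 10.0):
            shifted = make_regression(s=0.2, intercept=reg.intercept + math.log(c))
            assert estimate_wt(shifted, t_max_search=50.0).wt_estimate >= base

    def test_mrl_monotonicity(self):
        reg = make_regression(s=0.2)
        wts = [estimate_wt(reg, mrl=m, t_max_search=50.0).wt_estimate
               for m in (10.0, 50.0, 200.0)]
        assert wts[0] >= wts[1] >= wts[2]

    def test_degenerate_s_limit(self):
        reg0 = make_regression(s=1e-12)
        res = estimate_wt(reg0)
        line_cross = (math.log(0.05) - reg0.intercept) / reg0.slope
        assert res.wt_estimate == pytest.approx(line_cross, abs=1e-4)

    def test_zero_when_already_below(self):
        reg = make_regression(intercept=math.log(0.001), s=0.01)
        assert estimate_wt(reg).wt_estimate == 0.0

    def test_errors(self):
        with pytest.raises(NotEstimableError):
            estimate_wt(make_regression(slope=0.1))
        with pytest.raises(WindowError):
            estimate_wt(make_regression(slope=-1e-6, intercept=5.0, s=0.5),
                        t_max_search=1.0)


class TestModelInterface:
    def test_from_dataset_fit_and_wt(self, noisefree_datasets):
        ds = noisefree_datasets[2.0]
        model = WithdrawalTimeModel.from_dataset(ds, 2.0, "milk")
        res = model.fit()
        assert res.regression.slope < 0
        wt = res.estimate_wt(mrl=50.0)
        assert 1.0 <= wt.wt_reported <= 6.0
        text = res.summary()
        assert "WT estimate" in text and "slope" in text

    def test_exclusions_only_on_overflow(self, noisefree_datasets):
        """The pipeline-style helper applies the exclusion list only when
        the uncapped selection exceeds the time-point cap."""
        from milkpk.withdrawal import estimate_wt_from_dataset

        cfg = RunConfig(excluded_times=(0.17, 0.75))
        wt2 = estimate_wt_from_dataset(noisefree_datasets[2.0], 2.0, cfg)
        # dose 2 never overflows: 0.17 and 0.75 h stay in the fit
        assert 0.17 in wt2.regression.times_used
        wt4 = estimate_wt_from_dataset(noisefree_datasets[4.0], 4.0, cfg)
        assert 0.17 not in wt4.regression.times_used
        assert len(wt4.regression.times_used) == 7

    def test_default_exclusions_match_design(self):
        assert default_wt_exclusions(4.0)[:2] == (0.17, 0.75)
        assert all(t > 1.5 for t in default_wt_exclusions(2.0))

    def test_plot_smoke(self, noisefree_datasets):
        res = WithdrawalTimeModel.from_dataset(
            noisefree_datasets[2.0], 2.0, "milk").fit()
        ax = res.plot(mrl=50.0)
        assert ax.get_yscale() == "log"
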