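"""ROS plotting positions, imputation, log-normal fitting, summaries,
and the bootstrap KS goodness-of-fit test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pbsample as pb
from pbsample.censored import (
    DegenerateFitWarning,
    NotEstimableError,
    _ks_statistic_normal,
)
from pbsample.records import CensoredDataset, SampleRecord
from pbsample.synthetic import GeneratorConfig, generate_cohort

from conftest import make_dataset, random_censored_dataset


class TestPlottingPositions:
    def test_no_censoring_collapses_to_weibull(self):
        ds = make_dataset([3.0, 1.0, 4.0, 2.0], [])
        pos = pb.helsel_cohn_positions(ds)
        # Weibull positions r/(n+1) in value order
        assert pos == pytest.approx([0.6, 0.2, 0.8, 0.4])

    def test_single_limit_hand_computation(self, single_limit_dataset):
        # n=4, one limit at 1 ppb, detects {2, 5}, nondetects {<1, <1}:
        # P(exceed 1) = 2/4; detects at 1/2 + 1/2 * r/3, censored at
        # 1/2 * r/3 (hand-computed single-limit ROS table)
        pos = pb.helsel_cohn_positions(single_limit_dataset)
        assert pos == pytest.approx([2 / 3, 1 / 6, 5 / 6, 1 / 3])

    def test_two_limit_hand_computation(self, two_limit_dataset):
        # limits (1, 4): exceedance recursion gives P(>4)=1/7, P(>1)=17/35
        # (worked by hand through the threshold recursion)
        pos = pb.helsel_cohn_positions(two_limit_dataset)
        expected = [9 / 35, 6 / 35, 22 / 35, 12 / 35, 26 / 35, 3 / 7, 13 / 14]
        assert pos == pytest.approx(expected)

    def test_all_censored_not_estimable(self):
        ds = make_dataset([], [1.0, 1.0, 2.0])
        with pytest.raises(NotEstimableError):
            pb.helsel_cohn_positions(ds)

    @pytest.mark.parametrize("seed", range(8))
    def test_position_properties_multi_limit(self, seed):
        """Positions lie in (0,1); detect positions increase with value
        rank; each censored record sits below its own limit's
        non-exceedance probability (= the largest position any value
        below that limit could get)."""
        rng = np.random.default_rng(seed)
        ds = random_censored_dataset(rng, n=80)
        pos = pb.helsel_cohn_positions(ds)
        assert np.all((pos > 0) & (pos < 1))
        cens = ds.censored_mask
        det_order = np.argsort(ds.values[~cens], kind="stable")
        det_pos = pos[~cens][det_order]
        assert np.all(np.diff(det_pos) >= 0)
        # censored record vs detects at/above its limit
        for i in np.flatnonzero(cens):
            above = pos[~cens][ds.values[~cens] >= ds.limits[i]]
            if above.size:
                assert pos[i] < above.min()


class TestRosImpute:
    def test_identity_on_complete_data(self):
        ds = make_dataset([1.0, 2.5, 7.0, 3.0, 9.0], [])
        assert pb.ros_impute(ds) is ds

    def test_three_point_hand_regression(self):
        # detects {2, 5, 9}, one nondetect <1: positions are
        # 0.25 + 0.1875 r for detects and 0.125 for the nondetect;
        # oracle = explicit normal-equations OLS on the 3 detect points
        ds = make_dataset([2.0, 5.0, 9.0], [1.0])
        z = stats.norm.ppf([0.4375, 0.625, 0.8125])
        y = np.log([2.0, 5.0, 9.0])
        slope = np.sum((z - z.mean()) * (y - y.mean())) / np.sum((z - z.mean()) ** 2)
        intercept = y.mean() - slope * z.mean()
        expected = np.exp(intercept + slope * stats.norm.ppf(0.125))
        imp = pb.ros_impute(ds)
        imputed = [r for r in imp if r.imputed]
        assert len(imputed) == 1
        assert imputed[0].reported_value == pytest.approx(expected, rel=1e-12)
        assert imputed[0].censored  # flag preserved alongside imputed=True

    def test_detects_never_altered(self):
        rng = np.random.default_rng(4)
        ds = random_censored_dataset(rng, n=100)
        imp = pb.ros_impute(ds)
        cens = ds.censored_mask
        assert np.array_equal(imp.values[~cens], ds.values[~cens])
        assert np.all(imp.values > 0)

    def test_parameter_recovery_single_component(self):
        cfg = GeneratorConfig(
            n_samples=2000, weights=(1.0,),
            components=(pb.LognormalFit(0.0, 1.0),),
            censoring_schedule=((1.0, 1.0),), seed=11,
        )
        imp = pb.ros_impute(generate_cohort(cfg))
        logs = np.log(imp.values)
        assert logs.mean() == pytest.approx(0.0, abs=0.05)
        assert logs.std(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_imputed_above_limit_clamped_with_warning(self):
        # high detects force the fitted line above the tiny limit
        ds = make_dataset([10.0, 20.0, 30.0, 40.0], [0.5])
        with pytest.warns(UserWarning, match="clamped"):
            imp = pb.ros_impute(ds)
        val = [r.reported_value for r in imp if r.imputed][0]
        assert val == pytest.approx(0.999 * 0.5)

    def test_too_few_distinct_detects(self):
        with pytest.raises(NotEstimableError):
            pb.ros_impute(make_dataset([2.0, 2.0], [1.0]))

    def test_adding_top_detect_cannot_lower_fitted_p90(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ds = random_censored_dataset(rng, n=50)
            fit = pb.fit_lognormal_mle(pb.ros_impute(ds).values)
            bigger = ds.with_records(
                list(ds.records)
                + [SampleRecord(2 * ds.values.max(), False, 1.0)]
            )
            fit2 = pb.fit_lognormal_mle(pb.ros_impute(bigger).values)
            assert fit2.quantile(0.9) >= fit.quantile(0.9)


class TestFitLognormalMle:
    def test_constant_data_degenerate_warning(self):
        with pytest.warns(DegenerateFitWarning):
            fit = pb.fit_lognormal_mle([np.e] * 4)
        assert fit.mu == pytest.approx(1.0)
        assert fit.sigma == 0.0

    def test_two_point_closed_form(self):
        fit = pb.fit_lognormal_mle([1.0, np.exp(2.0)])
        assert fit.mu == pytest.approx(1.0)
        assert fit.sigma == pytest.approx(np.sqrt(2.0))

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(2)
        vals = np.exp(0.5 + 1.2 * rng.standard_normal(100000))
        fit = pb.fit_lognormal_mle(vals)
        assert fit.mu == pytest.approx(0.5, abs=0.02)
        assert fit.sigma == pytest.approx(1.2, abs=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pb.fit_lognormal_mle([1.0, -2.0])
        with pytest.raises(NotEstimableError):
            pb.fit_lognormal_mle([1.0])


class TestSummaryStats:
    def test_median_below_rl(self):
        ds = make_dataset([2.0, 3.0, 4.0, 5.0], [1.0] * 6)
        s = pb.summary_stats(ds)
        assert s.n == 10 and s.n_bdl == 6
        assert s.frac_bdl == pytest.approx(0.6)
        assert s.median_below_rl and s.median is None

    def test_countup_p90_of_ten_detects(self):
        s = pb.summary_stats(make_dataset(range(1, 11), []))
        assert s.p90_empirical == pytest.approx(9.0)

    def test_single_detect(self):
        s = pb.summary_stats(make_dataset([5.0], []))
        assert (s.n, s.frac_bdl, s.median) == (1, 0.0, 5.0)
        assert s.p90_empirical is None

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            pb.summary_stats(CensoredDataset([]))


class TestKsGof:
    def test_statistic_matches_scipy_definition(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            vals = np.exp(0.3 + 0.8 * rng.standard_normal(40))
            fit = pb.LognormalFit(0.3, 0.8)
            ours = _ks_statistic_normal(np.log(vals), fit.mu, fit.sigma)[0]
            ref = stats.kstest(np.log(vals), stats.norm(0.3, 0.8).cdf).statistic
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_level_under_the_null(self):
        # data drawn from the fitted family: bootstrap p > 0.05 nearly always
        rng = np.random.default_rng(5)
        keep = 0
        for s in range(30):
            vals = np.exp(0.2 + 1.1 * rng.standard_normal(500))
            fit = pb.fit_lognormal_mle(vals)
            res = pb.ks_gof(vals, fit, n_boot=200, seed=s)
            keep += res.pvalue > 0.05
        assert keep >= 27  # >= 90% of runs

    def test_power_against_separated_mixture(self):
        rng = np.random.default_rng(8)
        comp = rng.choice(2, p=[0.5, 0.5], size=500)
        logs = np.where(comp == 0, -2.0 + 0.3 * rng.standard_normal(500),
                        2.0 + 0.3 * rng.standard_normal(500))
        vals = np.exp(logs)
        fit = pb.fit_lognormal_mle(vals)
        res = pb.ks_gof(vals, fit, n_boot=300, seed=1)
        assert res.pvalue < 0.01

    def test_degenerate_and_warning_paths(self):
        vals = np.exp(np.random.default_rng(0).standard_normal(50))
        with pytest.raises(NotEstimableError):
            pb.ks_gof(vals, pb.LognormalFit(0.0, 0.0))
        with pytest.warns(UserWarning, match="n_boot"):
            pb.ks_gof(vals, pb.LognormalFit(0.0, 1.0), n_boot=50, seed=0)
        assert "independence" in pb.ks_gof(vals, pb.LognormalFit(0.0, 1.0),
                                           n_boot=100, seed=0).warning


class TestModelInterface:
    def test_fit_results_and_summary(self):
        rng = np.random.default_rng(10)
        ds = random_censored_dataset(rng, n=300)
        res = pb.CensoredLognormal(ds).fit(gof_boot=100, seed=0)
        assert res.params.method == "ros_regression"
        assert res.imputed_dataset.n_censored == ds.n_censored
        assert res.quantile(0.9) > res.quantile(0.5)
        text = res.summary()
        assert "sigma" in text and "censored" in text
        assert res.gof is not None

    def test_parameter_recovery_property(self):
        """Over seeded 40-60%-censored cohorts, ROS recovers (mu, sigma)
        with small median absolute error (full 200-cohort version runs
        in the acceptance suite)."""
        errs = []
        for seed in range(20):
            cfg = GeneratorConfig(
                n_samples=500, weights=(1.0,),
                components=(pb.LognormalFit(0.0, 1.0),),
                censoring_schedule=((1.0, 1.0),), seed=seed,
            )
            res = pb.CensoredLognormal(generate_cohort(cfg)).fit()
            errs.append((abs(res.params.mu), abs(res.params.sigma - 1.0)))
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.1)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.floats(0.1, 1000.0), min_size=2, max_size=40, unique=True),
       st.integers(0, 5))
def test_positions_bounds_property(detect_values, n_cens):
    """For any detects plus nondetects at 1 ppb, every position lies
    strictly inside (0, 1) and ROS output is positive."""
    ds = make_dataset(detect_values, [1.0] * n_cens)
    pos = pb.helsel_cohn_positions(ds)
    assert np.all((pos > 0) & (pos < 1))
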