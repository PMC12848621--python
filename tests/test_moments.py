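"""Population central moments, group aggregation, and trend fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmpolar.moments import (
    FitResult,
    central_moments,
    fit_exponential,
    fit_linear,
    bootstrap_beta_interval,
    moments_by_group,
    parse_trend_table,
    render_trend_table,
    trend_table,
)
from mmpolar.reconstruction import SampleMeta


def naive_moments(x):
    """Independent summation oracle for the four population moments."""
    n = len(x)
    mu = sum(x) / n
    sigma = (sum((v - mu) ** 2 for v in x) / n) ** 0.5
    skew = sum((v - mu) ** 3 for v in x) / (n * sigma**3)
    kurt = sum((v - mu) ** 4 for v in x) / (n * sigma**4)
    return mu, sigma, skew, kurt


class TestCentralMoments:
    def test_symmetric_two_point_mass(self):
        s = central_moments(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert s.mean == 0.0
        assert s.std == 1.0
        assert s.skewness == 0.0
        assert s.kurtosis == 1.0

    def test_bernoulli_quarter_closed_form(self):
        # Bernoulli(p) oracle: skew = (1-2p)/sqrt(pq), kurt = 3 + (1-6pq)/(pq).
        p, q = 0.25, 0.75
        s = central_moments(np.array([0.0, 0.0, 0.0, 1.0]))
        assert s.mean == pytest.approx(0.25)
        assert s.std == pytest.approx(np.sqrt(p * q))
        assert s.skewness == pytest.approx((1 - 2 * p) / np.sqrt(p * q))
        assert s.skewness == pytest.approx(1.1547, abs=1e-4)
        assert s.kurtosis == pytest.approx(3 + (1 - 6 * p * q) / (p * q))
        assert s.kurtosis == pytest.approx(2.3333, abs=1e-4)

    def test_agrees_with_naive_summation_oracle(self, rng):
        for n in (5, 100, 10_000):
            x = rng.normal(2.0, 3.0, size=n) ** 3
            s = central_moments(x)
            mu, sigma, skew, kurt = naive_moments(list(x))
            assert s.mean == pytest.approx(mu, abs=1e-12 * max(1, abs(mu)))
            assert s.std == pytest.approx(sigma, rel=1e-12)
            assert s.skewness == pytest.approx(skew, rel=1e-10)
            assert s.kurtosis == pytest.approx(kurt, rel=1e-10)

    def test_gaussian_large_sample_kurtosis_is_three(self):
        x = np.random.default_rng(123).standard_normal(1_000_000)
        s = central_moments(x)
        assert s.kurtosis == pytest.approx(3.0, abs=0.05)
        assert s.skewness == pytest.approx(0.0, abs=0.05)

    def test_affine_equivariance(self, rng):
        x = rng.gamma(2.0, size=500)
        a, b = 2.5, -7.0
        s0 = central_moments(x)
        s1 = central_moments(a * x + b)
        assert s1.mean == pytest.approx(a * s0.mean + b, rel=1e-10)
        assert s1.std == pytest.approx(a * s0.std, rel=1e-10)
        assert s1.skewness == pytest.approx(s0.skewness, rel=1e-9)
        assert s1.kurtosis == pytest.approx(s0.kurtosis, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            central_moments(np.array([1.0]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            central_moments(np.array([1.0, np.nan, 2.0]))

    def test_zero_spread_leaves_shape_moments_undefined(self):
        s = central_moments(np.array([2.0, 2.0, 2.0]))
        assert s.std == 0.0
        assert s.skewness is None and s.kurtosis is None


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(
        st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=50
    ).filter(lambda v: np.std(v) > 1e-6)
)
def test_pearson_bound_kurt_ge_skew_squared_plus_one(values):
    s = central_moments(np.array(values))
    assert s.kurtosis >= s.skewness**2 + 1 - 1e-9


class TestFitLinear:
    def test_constant_series(self):
        fit = fit_linear(np.array([75, 100, 125]), np.array([0.5, 0.5, 0.5]))
        assert fit.params[0] == pytest.approx(0.0, abs=1e-15)
        assert fit.params[1] == pytest.approx(0.5)

    def test_exact_line_recovered(self):
        x = np.arange(75, 250, 25, dtype=float)
        y = 0.002 * x + 0.1
        fit = fit_linear(x, y)
        assert fit.params[0] == pytest.approx(0.002, abs=1e-12)
        assert fit.params[1] == pytest.approx(0.1, abs=1e-10)
        assert fit.residual_norm < 1e-12

    def test_noisy_slope_within_three_standard_errors(self, rng):
        # Analytic OLS variance oracle: Var(slope) = sigma^2 / sum((x-xbar)^2).
        x = np.repeat(np.arange(75, 250, 25, dtype=float), 3)
        sigma = 0.05
        y = 0.002 * x + 0.1 + rng.normal(0, sigma, size=x.size)
        fit = fit_linear(x, y)
        se = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(fit.params[0] - 0.002) < 3 * se

    def test_single_x_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_linear(np.array([75.0, 75.0]), np.array([1.0, 2.0]))


class TestFitExponential:
    def test_noiseless_model_recovered(self):
        x = np.arange(75, 250, 25, dtype=float)
        y = 2.0 * np.exp(0.01 * x)
        fit = fit_exponential(x, y)
        alpha, beta, offset = fit.params
        assert fit.converged
        assert alpha == pytest.approx(2.0, abs=1e-6)
        assert beta == pytest.approx(0.01, abs=1e-9)
        assert offset == pytest.approx(0.0, abs=1e-5)

    def test_offset_allows_negative_values(self):
        x = np.arange(75, 250, 25, dtype=float)
        y = 0.5 * np.exp(0.012 * x) - 2.0
        fit = fit_exponential(x, y)
        assert fit.params[1] == pytest.approx(0.012, abs=1e-6)
        assert fit.params[2] == pytest.approx(-2.0, abs=1e-3)

    def test_constant_series_degenerate_branch(self):
        x = np.arange(75, 250, 25, dtype=float)
        fit = fit_exponential(x, np.full(x.size, 1.5))
        assert fit.status == "degenerate_constant"
        assert fit.params[1] == 0.0
        assert fit.params[2] == pytest.approx(1.5)

    def test_decreasing_series_negative_derivative(self):
        x = np.arange(75, 250, 25, dtype=float)
        y = 3.0 * np.exp(-0.01 * x) + 1.0
        fit = fit_exponential(x, y)
        assert fit.trend_sign == -1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 points"):
            fit_exponential(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))

    def test_recovered_beta_positive_and_in_bootstrap_interval(self, rng):
        # Generator ground truth + bootstrap oracle on a noisy rising series
        # (replicated design: 7 ages x 3, as in the cohort layout).
        x = np.repeat(np.arange(75, 250, 25, dtype=float), 3)
        beta_true = 0.012
        y = 0.1 * np.exp(beta_true * x) + 0.2 + rng.normal(0, 0.04, x.size)
        fit = fit_exponential(x, y)
        assert fit.params[1] > 0
        lo, hi = bootstrap_beta_interval(x, y, n_boot=100, seed=5)
        assert lo <= beta_true <= hi


class TestTrendSign:
    def test_rising_saturating_series_has_positive_trend_sign(self):
        # A concave rising curve is represented by alpha<0, beta<0 plus a
        # positive offset; the derivative sign must still read as increasing.
        x = np.arange(75, 250, 25, dtype=float)
        y = 2.0 - 1.5 * np.exp(-0.02 * x)
        fit = fit_exponential(x, y)
        assert fit.trend_sign == 1

    def test_linear_trend_sign(self):
        assert FitResult("linear", (0.1, 0.0), 0.0, True).trend_sign == 1
        assert FitResult("linear", (-0.1, 0.0), 0.0, True).trend_sign == -1


def _summary(param, age, value_shift, rng, wavelength=632, n=500):
    x = rng.normal(value_shift, 1.0, size=n)
    return central_moments(
        x, param, SampleMeta(f"a{age}", age, wavelength, "no_paraffin")
    )


class TestGrouping:
    def test_single_sample_groups_have_zero_error_bars(self, rng):
        summaries = [_summary("m44", age, age / 100, rng) for age in (75, 100, 125)]
        trend = moments_by_group(summaries)
        assert trend.ages == [75, 100, 125]
        for errs in trend.group_errors.values():
            assert np.allclose(errs, 0.0)
        assert np.allclose(
            trend.group_means["mean"], [s.mean for s in summaries]
        )

    def test_identical_replicates_leave_means_unchanged(self, rng):
        base = _summary("Delta", 150, 0.3, rng)
        trend = moments_by_group([base, base, base])
        assert trend.group_errors["mean"][0] == 0.0
        assert trend.group_means["mean"][0] == base.mean
        assert trend.n_samples == {150: 3}

    def test_group_means_match_direct_recomputation(self, rng):
        summaries = []
        per_age = {}
        for age in (75, 100, 125, 150):
            vals = []
            for _ in range(3):
                s = _summary("m22", age, 0.0, rng)
                summaries.append(s)
                vals.append(s.skewness)
            per_age[age] = np.mean(vals)
        trend = moments_by_group(summaries)
        for k, age in enumerate(trend.ages):
            assert trend.group_means["skewness"][k] == pytest.approx(per_age[age])

    def test_mixed_parameters_rejected(self, rng):
        with pytest.raises(ValueError, match="[Mm]ixed param"):
            moments_by_group(
                [_summary("m22", 75, 0, rng), _summary("m44", 75, 0, rng)]
            )

    def test_mixed_wavelengths_rejected(self, rng):
        with pytest.raises(ValueError, match="[Mm]ixed wavelength"):
            moments_by_group(
                [
                    _summary("m22", 75, 0, rng, wavelength=445),
                    _summary("m22", 75, 0, rng, wavelength=632),
                ]
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            moments_by_group([])


class TestTrendTable:
    def test_layout_single_parameter_single_age(self, rng):
        trend = moments_by_group([_summary("R", 100, 0.6, rng)])
        table = trend_table([trend])
        assert list(table["moment"]) == ["Mean", "Std", "Skew", "Kurt"]
        assert "100" in table.columns

    def test_full_ladder_layout(self, rng):
        ages = (75, 100, 125, 150, 175, 200, 225)
        trends = []
        for p in ("R", "P", "D", "Delta"):
            trends.append(
                moments_by_group([_summary(p, a, a / 200, rng) for a in ages])
            )
        table = trend_table(trends)
        assert len(table) == 4 * 4  # 4 parameters x 4 moment rows
        age_cols = [c for c in table.columns if c.isdigit()]
        assert age_cols == [str(a) for a in ages]  # ascending
        text = render_trend_table(table)
        assert "Delta" in text and "Kurt" in text

    def test_csv_round_trip(self, rng):
        ages = (75, 100, 125)
        trend = moments_by_group([_summary("D", a, 0.1, rng) for a in ages])
        table = trend_table([trend])
        back = parse_trend_table(table.to_csv(index=False))
        pd.testing.assert_frame_equal(back, table)


class TestTrendRecoveryOnSyntheticSeries:
    def test_injected_sign_pattern_recovered(self, rng):
        # Positive-beta exponential skewness growth plus negative linear
        # kurtosis drift: the fitted signs must match the injected ones in
        # >= 95% of seeded replicates.
        x = np.repeat(np.arange(75, 250, 25, dtype=float), 3)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            r = np.random.default_rng(500 + rep)
            skew = 0.05 * np.exp(0.01 * x) + r.normal(0, 0.08, x.size)
            kurt = 5.0 - 0.006 * x + r.normal(0, 0.25, x.size)
            ok = fit_exponential(x, skew).trend_sign == 1
            ok &= fit_linear(x, kurt).trend_sign == -1
            hits += ok
        assert hits >= 95
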