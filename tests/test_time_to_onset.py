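"""Onset-day rules, quantile summaries and Weibull fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.time_to_onset import (
    BETA_BOUNDS,
    FitError,
    classify_failure_type,
    compute_onsets,
    onset_days,
    summarize_tto,
    weibull_fit,
    weibull_loglik,
    weibull_median,
)


class TestOnsetDays:
    def test_same_day_onset_is_half_day(self):
        assert onset_days("2020-01-01", ["2020-01-01"]).days == 0.5

    def test_half_day_offset(self):
        assert onset_days("2020-01-10", ["2020-01-01"]).days == 9.5

    def test_multiple_starts_use_earliest_on_or_before_onset(self):
        res = onset_days("2020-03-05", ["2020-01-01", "2020-03-01"])
        assert res.days == 64.5  # from 2020-01-01 (leap year)

    def test_latest_rule_switches_choice(self):
        res = onset_days("2020-03-05", ["2020-01-01", "2020-03-01"], start_rule="latest")
        assert res.days == 4.5

    def test_cap_excludes_long_delays(self):
        res = onset_days("2020-06-01", ["2018-01-01"])
        assert res.excluded and res.reason == "exceeds_cap"

    def test_month_precision_onset_excluded(self):
        res = onset_days("2020-01", ["2020-01-01"])
        assert res.excluded and res.reason == "onset_not_day_precision"

    def test_month_precision_starts_excluded(self):
        res = onset_days("2020-01-10", ["2020-01", ""])
        assert res.excluded and res.reason == "no_day_precision_start"

    def test_start_after_onset_excluded(self):
        res = onset_days("2020-01-10", ["2020-02-01"])
        assert res.excluded and res.reason == "no_start_on_or_before_onset"

    def test_later_start_ignored_when_earlier_exists(self):
        # a start after the onset must not disqualify the pair
        res = onset_days("2020-01-10", ["2020-01-05", "2020-06-01"])
        assert res.days == 5.5


def test_exclusion_bookkeeping_is_exhaustive(small_synth):
    from pvsignal.analysis_builder import build_pairs

    db, _ = small_synth
    pairs = build_pairs(db)
    obs, exc = compute_onsets(pairs)
    assert len(obs) + len(exc) == len(pairs)
    assert set(exc.reason) <= {
        "onset_not_day_precision",
        "no_day_precision_start",
        "no_start_on_or_before_onset",
        "exceeds_cap",
    }
    assert (obs.days >= 0.5).all() and (obs.days <= 730).all()


class TestSummaries:
    def test_single_value(self):
        s = summarize_tto([0.5])
        assert (s["median"], s["q1"], s["q3"]) == (0.5, 0.5, 0.5)

    def test_odd_length_median(self):
        # mirrors a published vomiting profile: median 1.5, IQR 0.5-7.5
        s = summarize_tto([0.5, 1.5, 7.5])
        assert s["median"] == 1.5
        assert (s["q1"], s["q3"]) == (1.0, 4.5)

    def test_matches_sort_based_quantile_oracle(self):
        rng = np.random.default_rng(3)
        t = rng.gamma(2.0, 30.0, size=200)
        s = summarize_tto(t)
        x = np.sort(t)

        def type7(p):
            h = (len(x) - 1) * p
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])

        assert s["median"] == pytest.approx(type7(0.5), rel=1e-12)
        assert s["q1"] == pytest.approx(type7(0.25), rel=1e-12)
        assert s["q3"] == pytest.approx(type7(0.75), rel=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_tto([])


def _grid_mle(t):
    """Coarse-to-fine grid-search MLE, independent of the profile solver."""
    t = np.asarray(t, float)
    best = (-np.inf, None, None)
    for beta in np.geomspace(BETA_BOUNDS[0], BETA_BOUNDS[1], 4000):
        alpha = float(np.mean(t**beta)) ** (1.0 / beta)
        ll = weibull_loglik(t, alpha, beta)
        if ll > best[0]:
            best = (ll, alpha, beta)
    return best


class TestWeibullFit:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(42)
        t = 50.0 * rng.weibull(1.5, size=500)
        fit = weibull_fit(t)
        assert fit.alpha == pytest.approx(50.0, rel=0.10)
        assert fit.beta == pytest.approx(1.5, rel=0.10)
        # at least as good as an independent grid search
        ll_grid, _, _ = _grid_mle(t)
        assert fit.loglik >= ll_grid - 1e-6

    def test_exponential_special_case_beta_ci_contains_one(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(30.0, size=500)
        fit = weibull_fit(t)
        assert fit.beta_ci[0] < 1.0 < fit.beta_ci[1]

    def test_degenerate_sample_hits_shape_cap(self):
        fit = weibull_fit([7.5] * 10)
        assert fit.beta == BETA_BOUNDS[1]
        assert fit.alpha == pytest.approx(7.5, rel=1e-6)
        assert fit.beta_ci == (fit.beta, fit.beta)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(11)
        t = 20.0 * rng.weibull(1.2, size=80)
        f1 = weibull_fit(t)
        f2 = weibull_fit(k * t)
        assert f2.alpha == pytest.approx(k * f1.alpha, rel=1e-6)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-6)

    def test_fitted_median_tracks_empirical_median(self):
        rng = np.random.default_rng(9)
        t = 80.0 * rng.weibull(1.3, size=4000)
        fit = weibull_fit(t)
        assert weibull_median(fit.alpha, fit.beta) == pytest.approx(
            float(np.median(t)), rel=0.05
        )

    def test_matches_scipy_mle_cross_check(self):
        from scipy import stats

        rng = np.random.default_rng(101)
        t = 35.0 * rng.weibull(0.8, size=300)
        fit = weibull_fit(t)
        shape, _, scale = stats.weibull_min.fit(t, floc=0)
        assert fit.beta == pytest.approx(shape, rel=1e-4)
        assert fit.alpha == pytest.approx(scale, rel=1e-4)

    def test_too_few_or_nonpositive_observations_error(self):
        with pytest.raises(FitError):
            weibull_fit([1.0, 2.0])
        with pytest.raises(FitError):
            weibull_fit([1.0, 0.0, 2.0])


@pytest.mark.parametrize(
    "ci, expected",
    [
        ((0.41, 0.70), "early_failure"),
        ((1.21, 1.73), "wear_out"),
        ((0.88, 1.88), "random"),
    ],
)
def test_failure_type_classification(ci, expected):
    assert classify_failure_type(ci) == expected
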