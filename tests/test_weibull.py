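"""Time-to-onset extraction, Weibull MLE and onset-pattern classification."""

import math

import numpy as np
import pytest

from srsignal.report_store import TermMap
from srsignal.weibull import (
    DegenerateSampleError,
    TtoSample,
    WeibullFit,
    classify_pattern,
    extract_tto,
    fit_weibull,
    tto_to_frame,
    weibull_quantile,
)

from conftest import db_from_rows

TM = TermMap({"hypopituitarism": "aph", "rash": "skin"})


def make_fit(beta_ci, beta=None, alpha=100.0):
    beta = beta if beta is not None else float(np.sqrt(beta_ci[0] * beta_ci[1]))
    return WeibullFit("d", "h", 100, alpha, beta, (alpha * 0.9, alpha * 1.1),
                      tuple(beta_ci), -500.0, "indeterminate")


class TestExtractTto:
    def tto_db(self):
        cases = [(f"c{i}", "women") for i in range(1, 8)]
        drugs = [("c1", "ipilimumab", "suspect", "2020-01-01"),
                 ("c2", "ipilimumab", "suspect", "2020-01-10"),
                 ("c3", "ipilimumab", "suspect", "2020-02-01"),
                 ("c4", "ipilimumab", "suspect", None),       # missing start
                 ("c5", "ipilimumab", "suspect", "2020-03-01"),
                 ("c6", "ipilimumab", "suspect", "2020-04-01"),
                 ("c7", "ipilimumab", "concomitant", "2020-01-01")]
        events = [("c1", "hypopituitarism", "2020-01-01"),   # same day -> 1
                  ("c2", "hypopituitarism", "2020-01-05"),   # onset before start
                  ("c3", "hypopituitarism", "2020-03-01"),   # 29 + 1 days
                  ("c4", "hypopituitarism", "2020-05-01"),
                  ("c5", "hypopituitarism", None),           # missing onset
                  ("c6", "hypopituitarism", "2020-04-11"),   # 10 + 1 days
                  ("c7", "hypopituitarism", "2020-02-01")]   # not suspect-exposed
        return db_from_rows(cases, drugs, events)

    def test_latency_conventions_and_exclusions(self):
        sample = extract_tto(self.tto_db(), "ipilimumab", TM, "aph")
        assert sorted(sample.days) == [1, 11, 30]
        assert sample.n_used == 3
        assert sample.n_excluded_missing == 2     # c4 (start), c5 (onset)
        assert sample.n_excluded_nonpositive == 1  # c2

    def test_earliest_dates_win(self):
        cases = [("c1", "men")]
        drugs = [("c1", "ipilimumab", "suspect", "2020-02-01"),
                 ("c1", "ipilimumab", "suspect", "2020-01-01")]
        events = [("c1", "hypopituitarism", "2020-03-01"),
                  ("c1", "hypopituitarism", "2020-01-31")]
        sample = extract_tto(db_from_rows(cases, drugs, events), "ipilimumab",
                             TM, "aph")
        assert sample.days == (31,)

    def test_empty_sample_allowed(self):
        db = db_from_rows([("c1", "men")], [("c1", "x", "suspect", None)],
                          [("c1", "rash", None)])
        sample = extract_tto(db, "x", TM, "aph")
        assert sample.n_used == 0


class TestFitWeibull:
    def test_parameter_recovery_with_known_truth(self):
        rng = np.random.default_rng(42)
        days = np.ceil(100.0 * rng.weibull(1.5, size=500))
        fit = fit_weibull(TtoSample("d", "h", tuple(days), 0, 0))
        assert fit.alpha == pytest.approx(100.0, rel=0.10)
        assert fit.beta == pytest.approx(1.5, rel=0.10)
        assert fit.alpha_ci[0] < 100.0 < fit.alpha_ci[1]
        assert fit.beta_ci[0] < 1.5 < fit.beta_ci[1]
        assert fit.pattern == "wear_out"

    def test_matches_independent_survival_fitter(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        days = np.ceil(80.0 * rng.weibull(1.3, size=300))
        fit = fit_weibull(TtoSample("d", "h", tuple(days), 0, 0))
        wf = lifelines.WeibullFitter().fit(days)
        assert fit.alpha == pytest.approx(wf.lambda_, rel=1e-3)
        assert fit.beta == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.log_likelihood == pytest.approx(wf.log_likelihood_, rel=1e-6)

    def test_exponential_coverage_of_the_shape_ci(self):
        rng = np.random.default_rng(2024)
        covered = 0
        for _ in range(100):
            days = rng.exponential(scale=50.0, size=200)
            fit = fit_weibull(TtoSample("d", "h", tuple(days), 0, 0))
            if fit.beta_ci[0] <= 1.0 <= fit.beta_ci[1]:
                covered += 1
        assert covered >= 90

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        days = 30.0 * rng.weibull(2.0, size=200)
        base = fit_weibull(TtoSample("d", "h", tuple(days), 0, 0))
        scaled = fit_weibull(TtoSample("d", "h", tuple(days * 7.0), 0, 0))
        assert scaled.alpha == pytest.approx(7.0 * base.alpha, rel=1e-4)
        assert scaled.beta == pytest.approx(base.beta, rel=1e-4)

    def test_reported_optimum_is_locally_optimal(self):
        rng = np.random.default_rng(9)
        days = np.asarray(sorted(np.ceil(120.0 * rng.weibull(1.6, size=150))))
        fit = fit_weibull(TtoSample("d", "h", tuple(days), 0, 0))

        def loglik(alpha, beta):
            z = days / alpha
            return float(np.sum(np.log(beta / alpha) + (beta - 1) * np.log(z)
                                - z ** beta))

        assert fit.log_likelihood == pytest.approx(loglik(fit.alpha, fit.beta),
                                                   abs=1e-6)
        for _ in range(100):
            alpha = fit.alpha * math.exp(rng.normal(0.0, 0.2))
            beta = fit.beta * math.exp(rng.normal(0.0, 0.2))
            assert fit.log_likelihood >= loglik(alpha, beta)

    def test_small_samples_are_not_available(self):
        fit = fit_weibull(TtoSample("d", "h", (3, 9, 27), 0, 0), min_n=5)
        assert fit.pattern == "not_available"
        assert math.isnan(fit.alpha)

    def test_zero_spread_sample_refused(self):
        with pytest.raises(DegenerateSampleError, match="zero-spread|equal"):
            fit_weibull(TtoSample("d", "h", (30,) * 20, 0, 0))

    def test_nonpositive_latency_rejected(self):
        with pytest.raises(ValueError):
            fit_weibull([0, 5, 10])


class TestClassifyPattern:
    @pytest.mark.parametrize("beta_ci,expected", [
        ((1.36, 1.73), "wear_out"),
        ((0.92, 4.49), "indeterminate"),
        ((0.30, 0.80), "early_failure"),
        ((0.99, 1.01), "indeterminate"),
    ])
    def test_interval_position_drives_the_pattern(self, beta_ci, expected):
        assert classify_pattern(make_fit(beta_ci)) == expected

    def test_unavailable_fit_stays_unavailable(self):
        assert classify_pattern(WeibullFit.unavailable("d", "h", 2)) == "not_available"


class TestWeibullQuantile:
    def test_returns_alpha_at_the_characteristic_fraction(self):
        fit = make_fit((1.3, 1.8), beta=1.54, alpha=97.3)
        assert weibull_quantile(fit, 1.0 - math.exp(-1.0)) == pytest.approx(97.3)

    def test_published_scale_implies_the_median_onset(self):
        # alpha = 97.3 days, beta = 1.54: half of onsets by ~77 days
        fit = make_fit((1.36, 1.73), beta=1.54, alpha=97.3)
        assert weibull_quantile(fit, 0.5) == pytest.approx(76.7, abs=0.1)

    def test_strictly_increasing_in_p(self):
        fit = make_fit((1.3, 1.8), beta=1.54, alpha=97.3)
        qs = [weibull_quantile(fit, p) for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert qs == sorted(qs) and len(set(qs)) == len(qs)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_probability_domain_enforced(self, p):
        with pytest.raises(ValueError):
            weibull_quantile(make_fit((1.3, 1.8)), p)


def test_tto_frame_layout():
    fits = [make_fit((1.36, 1.73)), WeibullFit.unavailable("d2", "h", 0)]
    frame = tto_to_frame(fits)
    assert list(frame.columns) == ["drug", "hlt", "n_used", "alpha", "alpha_low",
                                   "alpha_high", "beta", "beta_low", "beta_high",
                                   "pattern"]
    assert frame.loc[1, "pattern"] == "not_available"
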