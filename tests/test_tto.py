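import datetime
import math

import numpy as np
import pytest

from pvfaers.tto import (
    TTOSample,
    build_tto_sample,
    classify_failure,
    compute_tto,
    fit_weibull,
    tto_summary,
)


class TestComputeTto:
    def test_calendar_arithmetic(self):
        assert compute_tto("20230110", ["20230101"]) == (9, None)

    def test_same_day_onset_retained_as_zero(self):
        assert compute_tto("20230101", ["20230101"]) == (0, None)

    def test_event_before_start_excluded(self):
        assert compute_tto("20221231", ["20230101"]) == (None, "negative")

    def test_earliest_valid_start_used(self):
        assert compute_tto("20230110", ["20230105", "20230101", ""]) == (9, None)

    @pytest.mark.parametrize(
        "event,starts,reason",
        [
            ("", ["20230101"], "missing_event"),
            ("2023", ["20230101"], "malformed"),
            ("20230110", [""], "missing_start"),
            ("20230110", [], "missing_start"),
            ("20230110", ["202301"], "malformed"),
        ],
    )
    def test_exclusion_reasons(self, event, starts, reason):
        assert compute_tto(event, starts) == (None, reason)

    def test_date_objects_accepted(self):
        t, r = compute_tto(datetime.date(2023, 1, 10), [datetime.date(2023, 1, 1)])
        assert (t, r) == (9, None)

    def test_sample_accounting(self):
        s = build_tto_sample(
            "x",
            ["20230110", "", "20221231", "20230105"],
            [["20230101"], ["20230101"], ["20230101"], ["20230101"]],
        )
        assert s.n_valid == 2
        assert s.n_excluded["missing_event"] == 1
        assert s.n_excluded["negative"] == 1
        assert s.n_total == 4


class TestTtoSummary:
    def test_median_of_zeros(self):
        out = tto_summary(np.array([0.0, 0.0, 10.0]))
        assert out["median"] == 0.0

    def test_interpolated_quartiles_1_to_100(self):
        out = tto_summary(np.arange(1.0, 101.0))
        assert out["median"] == pytest.approx(50.5)
        assert out["q1"] == pytest.approx(25.75)
        assert out["q3"] == pytest.approx(75.25)

    def test_band_enumeration(self):
        out = tto_summary(np.array([15.0, 45.0, 400.0]))
        assert out["bands"]["0-30d"] == 1
        assert out["bands"]["31-60d"] == 1
        assert out["bands"]["360d<"] == 1
        assert sum(out["bands"].values()) == 3

    def test_band_edges_inclusive(self):
        out = tto_summary(np.array([0.0, 30.0, 31.0, 360.0, 361.0]))
        assert out["bands"]["0-30d"] == 2
        assert out["bands"]["31-60d"] == 1
        assert out["bands"]["181-360d"] == 1
        assert out["bands"]["360d<"] == 1

    def test_empty_sample_all_missing(self):
        out = tto_summary(TTOSample("x", np.array([])))
        assert out["n"] == 0
        assert math.isnan(out["median"])


class TestFitWeibull:
    def test_exponential_data_recovers_shape_one(self):
        rng = np.random.default_rng(101)
        x = np.rint(rng.exponential(120.0, size=2000))
        f = fit_weibull(x)
        assert f.converged
        assert 0.95 <= f.beta <= 1.05
        assert f.beta_lo <= 1.0 <= f.beta_hi
        assert f.failure_type == "random"

    def test_early_failure_recovery(self):
        rng = np.random.default_rng(202)
        x = 150.0 * rng.weibull(0.65, size=2000)
        f = fit_weibull(x)
        assert f.converged
        assert f.beta_lo <= 0.65 <= f.beta_hi
        assert f.beta_hi < 1.0
        assert f.failure_type == "early"
        # day-rounded data (the FAERS case) still classifies as early,
        # with a small upward discretisation bias in beta
        f_days = fit_weibull(np.rint(x))
        assert f_days.failure_type == "early"
        assert abs(f_days.beta - f.beta) < 0.1

    def test_wear_out_recovery(self):
        rng = np.random.default_rng(303)
        x = np.rint(100.0 * rng.weibull(2.5, size=1000))
        f = fit_weibull(x)
        assert f.converged
        assert f.beta_lo > 1.0
        assert f.failure_type == "wear_out"

    def test_scipy_cross_check(self):
        from scipy import stats

        rng = np.random.default_rng(404)
        x = 80.0 * rng.weibull(0.7, size=1500) + 0.5
        f = fit_weibull(x, zero_replacement=0.5)
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        assert f.beta == pytest.approx(c, rel=1e-3)
        assert f.alpha == pytest.approx(scale, rel=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(505)
        x = 50.0 * rng.weibull(0.8, size=800) + 1.0
        f1 = fit_weibull(x)
        f2 = fit_weibull(7.0 * x)
        assert f2.alpha == pytest.approx(7.0 * f1.alpha, rel=1e-5)
        assert f2.beta == pytest.approx(f1.beta, rel=1e-5)

    def test_constant_sample_flagged(self):
        f = fit_weibull(np.full(100, 7.0))
        assert not f.converged
        assert f.failure_type is None

    def test_below_floor_not_fit(self):
        f = fit_weibull(np.arange(10.0), min_n=30)
        assert not f.converged

    def test_zero_replacement_recorded(self):
        rng = np.random.default_rng(606)
        x = np.rint(20.0 * rng.weibull(0.6, size=500))
        f = fit_weibull(x)
        assert f.zero_handling == "replace_0.5"
        assert f.converged

    def test_ci_coverage_over_replicates(self):
        """95% Wald CI on ln(beta) covers the true shape >= 90% of runs."""
        rng = np.random.default_rng(909)
        covered = total = 0
        for beta in (0.5, 1.0, 1.5):
            for _ in range(67):
                x = 100.0 * rng.weibull(beta, size=500)
                f = fit_weibull(np.where(x <= 0, 0.5, x))
                assert f.converged
                total += 1
                covered += f.beta_lo <= beta <= f.beta_hi
        assert covered / total >= 0.90


class TestClassifyFailure:
    @pytest.mark.parametrize(
        "beta,lo,hi,expected",
        [
            (0.68, 0.66, 0.69, "early"),
            (0.93, 0.87, 1.00, "random"),  # upper bound exactly 1 includes 1
            (1.03, 0.91, 1.16, "random"),
            (1.50, 1.20, 1.90, "wear_out"),
            (1.00, 1.00, 1.00, "random"),
        ],
    )
    def test_rule(self, beta, lo, hi, expected):
        assert classify_failure(beta, lo, hi) == expected

    def test_partition_of_ci_plane(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            lo = rng.uniform(0.1, 2.0)
            hi = lo + rng.uniform(0.0, 1.0)
            label = classify_failure((lo + hi) / 2, lo, hi)
            assert label in {"early", "random", "wear_out"}
            assert (label == "early") == (hi < 1)
            assert (label == "wear_out") == (lo > 1)

    def test_invalid_fit_rejected(self):
        with pytest.raises(ValueError):
            classify_failure(math.nan, 0.5, 1.5)
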