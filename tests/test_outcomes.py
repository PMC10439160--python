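"""Kaplan–Meier, log-rank and Cox fits against hand-written oracles."""

import numpy as np
import pandas as pd
import pytest

from capsulezone.errors import ValidationError
from capsulezone.outcomes import (
    PatientRecord,
    build_survival_report,
    cox_fit,
    km_estimate,
    logrank_test,
    records_to_frame,
)
from capsulezone.synthetic_cohort import GeneratorConfig, generate_cohort


def km_oracle(times, events):
    """Textbook product-limit estimate at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    out = {}
    for t in np.unique(times[events == 1]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / at_risk
        out[t] = s
    return out


def logrank_oracle(times, events, groups):
    """Observed-minus-expected chi-square for two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g1 = np.unique(groups)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        n = np.sum(times >= t)
        n1 = np.sum((times >= t) & (groups == g1))
        d = np.sum((times == t) & (events == 1))
        d1 = np.sum((times == t) & (events == 1) & (groups == g1))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for one covariate (brute force)."""
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def make_records(times, events, pcts, **kw):
    return [
        PatientRecord(
            patient_id=f"p{i}", pct_encapsulated=float(p), os_time=float(t),
            os_event=int(e), hrfs_time=float(t), hrfs_event=int(e), **kw,
        )
        for i, (t, e, p) in enumerate(zip(times, events, pcts))
    ]


class TestKaplanMeier:
    def test_all_censored_survival_is_one(self):
        est = km_estimate([5, 10, 15], [0, 0, 0])["0"]
        assert np.allclose(est["survival"], 1.0)

    def test_three_events_by_hand(self):
        est = km_estimate([1, 2, 3], [1, 1, 1])["0"]
        lookup = dict(zip(est["time"], est["survival"]))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_matches_textbook_oracle_random(self, rng):
        times = rng.exponential(10, size=50).round(1) + 0.1
        events = rng.integers(0, 2, size=50)
        est = km_estimate(times, events)["0"]
        lookup = dict(zip(est["time"], est["survival"]))
        for t, s in km_oracle(times, events).items():
            assert lookup[t] == pytest.approx(s, rel=1e-9)

    def test_subject_order_invariance(self, rng):
        times = rng.exponential(10, size=30) + 0.1
        events = rng.integers(0, 2, size=30)
        perm = rng.permutation(30)
        a = km_estimate(times, events)["0"]
        b = km_estimate(times[perm], events[perm])["0"]
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1] * 2
        groups = [0] * 4 + [1] * 4
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_table(self, rng):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 0, 1]
        groups = ["a", "b", "a", "b", "a", "b"]
        chi2, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(logrank_oracle(times, events, groups), rel=1e-9)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            t1 = rng.exponential(1.0, 100)
            t2 = rng.exponential(5.0, 100)
            times = np.concatenate([t1, t2]) + 1e-3
            events = np.ones(200, dtype=int)
            groups = np.repeat([0, 1], 100)
            _, p = logrank_test(times, events, groups)
            hits += p < 0.001
        assert hits >= 19

    def test_label_permutation_invariance(self, rng):
        times = rng.exponential(5, 40) + 0.1
        events = rng.integers(0, 2, 40)
        groups = rng.integers(0, 2, 40)
        chi2a, pa = logrank_test(times, events, groups)
        chi2b, pb = logrank_test(times, events, 1 - groups)
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_empty_group_error(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCoxFit:
    def _toy(self):
        # 8 subjects, binary covariate, distinct times
        times = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 1, 0, 1, 0, 0, 0, 1])
        df = pd.DataFrame({
            "os_time": times, "os_event": events, "x": x,
        })
        return df, times, events, x

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_coefficient_matches_grid_search_oracle(self, ties):
        df, times, events, x = self._toy()
        fit = cox_fit(df, ["x"], endpoint="os", ties=ties)
        grid = np.arange(-4.0, 4.0, 1e-4)
        lls = [cox_partial_loglik(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert fit.coefficients["x"] == pytest.approx(beta_star, abs=1e-4)

    def test_efron_breslow_agree_without_ties(self):
        rng = np.random.default_rng(11)
        n = 60
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.5 * x)) + 1e-6
        events = (rng.random(n) < 0.7).astype(int)
        df = pd.DataFrame({"os_time": times, "os_event": events, "x": x})
        fe = cox_fit(df, ["x"], ties="efron")
        fb = cox_fit(df, ["x"], ties="breslow")
        assert fe.coefficients["x"] == pytest.approx(fb.coefficients["x"], abs=1e-5)
        assert fe.p_values["x"] == pytest.approx(fb.p_values["x"], abs=1e-4)

    def test_scale_equivariance_per_0_1_coding(self):
        recs = make_records(
            times=np.arange(1, 41), events=[1, 0] * 20,
            pcts=np.linspace(0, 100, 40),
        )
        df = records_to_frame(recs)
        df["encapsulation_per_1"] = df["pct_encapsulated"]
        fit_01 = cox_fit(df, ["encapsulation_per_0.1"])
        fit_1 = cox_fit(df, ["encapsulation_per_1"])
        assert fit_01.coefficients.iloc[0] == pytest.approx(
            10.0 * fit_1.coefficients.iloc[0], rel=1e-6
        )

    def test_hr_and_ci_consistency(self):
        df, *_ = self._toy()
        fit = cox_fit(df, ["x"])
        assert fit.hazard_ratios["x"] == pytest.approx(np.exp(fit.coefficients["x"]))
        assert fit.ci_lower["x"] <= fit.hazard_ratios["x"] <= fit.ci_upper["x"]

    def test_constant_covariate_rejected(self):
        df, *_ = self._toy()
        df["c"] = 1.0
        with pytest.raises(ValidationError):
            cox_fit(df, ["c"])

    def test_missing_covariates_dropped(self):
        df, *_ = self._toy()
        df.loc[0, "x"] = np.nan
        fit = cox_fit(df, ["x"])
        assert fit.n == 7
        assert fit.n_dropped_missing == 1

    def test_null_coverage_small_monte_carlo(self):
        """Null covariate: the 95% Wald CI covers HR=1 in ~95% of fits."""
        covered = 0
        n_sims = 40
        for seed in range(n_sims):
            cfg = GeneratorConfig(seed=seed, n_patients=150, log_hr_per_0_1=0.0)
            cohort, _ = generate_cohort(cfg)
            fit = cox_fit(cohort, ["encapsulation_per_0.1"])
            covered += fit.ci_lower.iloc[0] <= 1.0 <= fit.ci_upper.iloc[0]
        assert 0.85 <= covered / n_sims <= 1.0


class TestSurvivalReport:
    def test_full_report_on_synthetic_cohort(self):
        cohort, _ = generate_cohort(GeneratorConfig(seed=3, n_patients=200))
        report = build_survival_report(cohort, endpoint="os")
        assert set(report["km_by_stratum"]) == {"low", "medium", "high"}
        assert report["logrank_stratum"]["p"] < 0.5  # defined, sane
        hr = report["cox_continuous"].hazard_ratios.iloc[0]
        assert 0.8 < hr < 1.0  # protective encapsulation effect recovered
        assert report["cox_multivariate"] is not None

    def test_single_stratum_cohort_no_crash(self):
        recs = make_records(times=np.arange(1, 11), events=[1] * 10, pcts=[100.0] * 10)
        report = build_survival_report(recs)
        assert report["logrank_stratum"] is None
        assert report["cox_univariate_strata"] is None

    def test_stratum_hr_ordering(self):
        """With hazard decreasing in encapsulation, HR(high) < HR(medium) < 1."""
        cohort, _ = generate_cohort(GeneratorConfig(seed=17, n_patients=400))
        report = build_survival_report(cohort, endpoint="os")
        fit = report["cox_univariate_strata"]
        assert fit.hazard_ratios["encapsulation_high"] < fit.hazard_ratios["encapsulation_medium"] < 1.0
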