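import numpy as np
import pytest

from wsirisk.survival import (
    CoxResult,
    KMCurve,
    NonEstimableError,
    SurvivalRecord,
    ValidationError,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    median_survival,
)


def rec(t, e, g="low", i=[0]):
    i[0] += 1
    return SurvivalRecord(patient_id=f"p{i[0]}", time=t, event=e, group=g)


def random_records(rng, n, censor=True, group=None):
    out = []
    for k in range(n):
        t = float(rng.exponential(10.0))
        e = 1
        if censor and rng.random() < 0.3:
            e = 0
        g = group or ("high" if rng.random() < 0.5 else "low")
        out.append(SurvivalRecord(f"r{k}", max(t, 1e-6), e, g))
    return out


class TestSurvivalRecord:
    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalRecord("p", 0.0, 1)

    def test_bad_event_rejected(self):
        with pytest.raises(ValidationError):
            SurvivalRecord("p", 1.0, 2)


class TestKaplanMeier:
    def test_all_censored_survival_one(self):
        curve = km_estimate([rec(5, 0), rec(8, 0), rec(11, 0)])
        assert len(curve.times) == 0
        assert curve.survival_at(100) == 1.0

    def test_single_death_of_four(self):
        curve = km_estimate([rec(10, 1), rec(12, 0), rec(15, 0), rec(20, 0)])
        assert curve.survival_at(9.99) == 1.0
        assert curve.survival_at(10) == 0.75

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            records = random_records(rng, int(rng.integers(3, 40)), censor=False)
            curve = km_estimate(records)
            times = np.array([r.time for r in records])
            for t in curve.times:
                np.testing.assert_allclose(
                    curve.survival_at(t), (times > t).mean(), atol=1e-12
                )

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        records = random_records(rng, 30)
        shuffled = [records[i] for i in rng.permutation(30)]
        a, b = km_estimate(records), km_estimate(shuffled)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.survival, b.survival)

    def test_horizon_truncates(self):
        curve = km_estimate([rec(10, 1), rec(30, 1), rec(40, 0)], horizon=24)
        assert curve.times.max() <= 24

    def test_ties_decrement_simultaneously(self):
        curve = km_estimate([rec(5, 1), rec(5, 1), rec(5, 0), rec(9, 0)])
        assert curve.survival_at(5) == 0.5

    def test_matches_lifelines(self):
        import lifelines

        rng = np.random.default_rng(2)
        records = random_records(rng, 200)
        curve = km_estimate(records)
        kmf = lifelines.KaplanMeierFitter().fit(
            [r.time for r in records], [r.event for r in records]
        )
        for t in curve.times[:: max(len(curve.times) // 10, 1)]:
            np.testing.assert_allclose(
                curve.survival_at(t), float(kmf.predict(t)), atol=1e-10
            )


class TestMedianSurvival:
    def test_not_reached(self):
        curve = km_estimate([rec(10, 1)] + [rec(20, 0)] * 9)
        assert median_survival(curve) is None

    def test_boundary_convention_at_exactly_half(self):
        curve = km_estimate([rec(12, 1), rec(30, 0)])
        assert curve.survival_at(12) == 0.5
        assert median_survival(curve) == 12

    def test_exponential_analytic_median(self):
        rng = np.random.default_rng(3)
        lam = 0.05
        records = [
            SurvivalRecord(f"e{i}", float(rng.exponential(1 / lam)) + 1e-12, 1)
            for i in range(5000)
        ]
        med = median_survival(km_estimate(records))
        assert abs(med - np.log(2) / lam) / (np.log(2) / lam) < 0.10


class TestLogrank:
    def test_identical_groups_null(self):
        group = [rec(5, 1), rec(9, 1), rec(14, 0)]
        stat, p = logrank_test(group, list(group))
        assert stat == 0.0 and p == 1.0

    def test_six_patient_worked_example(self):
        """Independent O-E / V tabulation over the pooled risk sets."""
        a = [rec(1, 1, "a"), rec(2, 1, "a"), rec(3, 1, "a")]
        b = [rec(4, 1, "b"), rec(5, 1, "b"), rec(6, 1, "b")]
        # Manual tabulation: at each event time t the risk set holds
        # everyone with time >= t; one death each time.
        n_a, n_b = 3, 3
        o_minus_e, var = 0.0, 0.0
        for t, death_in_a in [(1, 1), (2, 1), (3, 1), (4, 0), (5, 0), (6, 0)]:
            n = n_a + n_b
            e_a = n_a / n
            o_minus_e += death_in_a - e_a
            var += (n_a / n) * (n_b / n)  # d=1: hypergeometric variance
            if death_in_a:
                n_a -= 1
            else:
                n_b -= 1
        expected = o_minus_e**2 / var
        stat, _ = logrank_test(a, b)
        assert abs(stat - expected) < 1e-10

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = random_records(rng, 25), random_records(rng, 30)
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0], abs=1e-12)

    def test_zero_events_warns(self):
        with pytest.warns(UserWarning):
            stat, p = logrank_test([rec(3, 0)], [rec(4, 0)])
        assert stat == 0.0 and p == 1.0

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(5)
        a, b = random_records(rng, 60), random_records(rng, 80)
        stat, p = logrank_test(a, b)
        ref = ll_logrank(
            [r.time for r in a], [r.time for r in b],
            [r.event for r in a], [r.event for r in b],
        )
        assert stat == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)


def breslow_grid_oracle(records, high_label="high", grid_step=1e-4):
    """Brute-force maximization of the Breslow partial likelihood on a
    beta grid, using the closed form for a binary covariate."""
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    x = np.array([1.0 if r.group == high_label else 0.0 for r in records])
    grid = np.arange(-3.0, 3.0 + grid_step, grid_step)
    loglik = np.zeros_like(grid)
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        n1 = x[at_risk].sum()
        n0 = at_risk.sum() - n1
        loglik += grid * x[dead].sum() - dead.sum() * np.log(n0 + n1 * np.exp(grid))
    return grid[np.argmax(loglik)]


class TestCox:
    def test_grid_oracle_agreement(self):
        rng = np.random.default_rng(6)
        tested = 0
        while tested < 20:
            records = random_records(rng, int(rng.integers(15, 40)))
            try:
                result = cox_fit(records, high_label="high")
            except (NonEstimableError, ValidationError):
                continue
            if abs(result.log_hazard_ratio) > 2.5:
                continue  # outside the oracle grid's interior
            beta_grid = breslow_grid_oracle(records)
            assert abs(result.log_hazard_ratio - beta_grid) < 2e-4
            tested += 1

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(7)
        records = random_records(rng, 80)
        forward = cox_fit(records, high_label="high")
        backward = cox_fit(records, high_label="low")
        assert forward.log_hazard_ratio == pytest.approx(
            -backward.log_hazard_ratio, abs=1e-8
        )
        assert forward.hazard_ratio == pytest.approx(
            1 / backward.hazard_ratio, rel=1e-8
        )

    def test_score_zero_at_optimum(self):
        rng = np.random.default_rng(8)
        records = random_records(rng, 100)
        result = cox_fit(records, high_label="high")
        times = np.array([r.time for r in records])
        events = np.array([r.event for r in records])
        x = np.array([1.0 if r.group == "high" else 0.0 for r in records])
        score = 0.0
        for t in np.unique(times[events == 1]):
            dead = (times == t) & (events == 1)
            at_risk = times >= t
            w = np.exp(result.log_hazard_ratio * x[at_risk])
            score += x[dead].sum() - dead.sum() * (w * x[at_risk]).sum() / w.sum()
        assert abs(score) < 1e-6

    def test_ci_brackets_hr(self):
        rng = np.random.default_rng(9)
        result = cox_fit(random_records(rng, 120), high_label="high")
        assert result.ci_low < result.hazard_ratio < result.ci_high
        assert result.hazard_ratio > 0

    def test_zero_events_not_estimable(self):
        records = [rec(5, 0, "low"), rec(6, 0, "high"), rec(7, 0, "low"), rec(8, 0, "high")]
        with pytest.raises(NonEstimableError):
            cox_fit(records, high_label="high")

    def test_event_free_group_not_estimable(self):
        records = [rec(5, 1, "high"), rec(6, 1, "high"), rec(7, 0, "low"), rec(8, 0, "low")]
        with pytest.raises(NonEstimableError):
            cox_fit(records, high_label="high")

    def test_matches_lifelines(self):
        import lifelines
        import pandas as pd

        rng = np.random.default_rng(10)
        records = random_records(rng, 300)
        result = cox_fit(records, high_label="high")
        df = pd.DataFrame(
            {
                "T": [r.time for r in records],
                "E": [r.event for r in records],
                "x": [1 if r.group == "high" else 0 for r in records],
            }
        )
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert result.log_hazard_ratio == pytest.approx(
            float(cph.params_.iloc[0]), abs=1e-6
        )
        assert result.se == pytest.approx(
            float(cph.standard_errors_.iloc[0]), abs=1e-6
        )

    def test_logrank_equals_cox_score_test_without_censoring_or_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            times = rng.exponential(10, size=40)
            while len(np.unique(times)) < 40:
                times = rng.exponential(10, size=40)
            groups = ["high" if i % 2 else "low" for i in range(40)]
            records = [
                SurvivalRecord(f"c{i}", float(t), 1, g)
                for i, (t, g) in enumerate(zip(times, groups))
            ]
            low = [r for r in records if r.group == "low"]
            high = [r for r in records if r.group == "high"]
            lr_stat, _ = logrank_test(low, high)
            score_stat = cox_score_test(records, high_label="high")
            assert abs(lr_stat - score_stat) < 1e-8
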