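"""SFO and bi-phasic decline fitting, DT50 derivation, overall half-life."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coformkin as ck
from coformkin.kinetics import BiphasicDeclineModel, SFODeclineModel

LN2 = float(np.log(2.0))


def bisect_half_life(curve, lo=0.0, hi=1e6, tol=1e-12):
    """Independent bisection oracle: time at which curve(t) = curve(0)/2."""
    target = curve(0.0) / 2.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if curve(mid) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestClosedForms:
    def test_sfo_predict_examples(self):
        p = ck.SfoParams(c0=19.0, k=LN2 / 5.0)
        assert ck.sfo_predict(p, 0.0) == pytest.approx(19.0)
        assert ck.sfo_predict(p, 5.0) == pytest.approx(9.5)
        assert ck.sfo_predict(p, 3.0) == pytest.approx(12.536, abs=5e-3)

    def test_sfo_strictly_decreasing(self):
        p = ck.SfoParams(c0=1.0, k=0.3)
        t = np.linspace(0, 30, 50)
        c = ck.sfo_predict(p, t)
        assert np.all(np.diff(c) < 0) and np.all(c > 0)

    @pytest.mark.parametrize("k, dt50", [(LN2, 1.0), (0.13863, 5.0)])
    def test_dt50_from_k(self, k, dt50):
        assert ck.dt50_from_k(k) == pytest.approx(dt50, rel=1e-4)

    def test_dt50_requires_decline(self):
        with pytest.raises(ValueError, match="no decline"):
            ck.dt50_from_k(0.0)

    @given(st.floats(min_value=1e-4, max_value=100.0))
    @settings(derandomize=True, max_examples=50)
    def test_dt50_identity(self, k):
        assert ck.dt50_from_k(k) * k == pytest.approx(LN2)


class TestOverallDt50:
    def test_sfo_limit(self):
        p = ck.BiphasicParams(c0=1.0, g=1.0, k1=0.5, k2=0.0)
        assert ck.overall_dt50(p) == pytest.approx(LN2 / 0.5)

    def test_equal_phase_example(self):
        # equal fast/slow weights, half-lives 1 d and 10 d
        p = ck.BiphasicParams(c0=1.0, g=0.5, k1=LN2 / 1.0, k2=LN2 / 10.0)
        assert ck.overall_dt50(p) == pytest.approx(2.60, abs=5e-3)

    def test_within_phase_bounds(self):
        p = ck.BiphasicParams(c0=3.0, g=0.7, k1=2.0, k2=0.05)
        t50 = ck.overall_dt50(p)
        assert LN2 / 2.0 <= t50 <= LN2 / 0.05

    def test_monotone_in_slow_rate(self):
        base = dict(c0=1.0, g=0.6, k1=1.0)
        t50s = [ck.overall_dt50(ck.BiphasicParams(k2=k2, **base)) for k2 in (0.01, 0.05, 0.2, 0.9)]
        assert all(a >= b for a, b in zip(t50s, t50s[1:]))

    def test_no_decline_rejected(self):
        with pytest.raises(ValueError):
            ck.overall_dt50(ck.BiphasicParams(c0=1.0, g=0.5, k1=0.0, k2=0.0))

    def test_persistent_plateau_rejected(self):
        # slow phase never declines and holds 60% of c0
        with pytest.raises(ValueError, match="50%"):
            ck.overall_dt50(ck.BiphasicParams(c0=1.0, g=0.4, k1=1.0, k2=0.0))

    def test_matches_bisection_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            g = rng.uniform(0.05, 0.95)
            k2 = rng.uniform(1e-3, 0.5)
            k1 = k2 + rng.uniform(1e-3, 5.0)
            p = ck.BiphasicParams(c0=rng.uniform(0.5, 50), g=g, k1=k1, k2=k2)
            oracle = bisect_half_life(lambda t: ck.biphasic_predict(p, t), hi=LN2 / k2 + 1.0)
            assert ck.overall_dt50(p) == pytest.approx(oracle, abs=1e-6)


class TestSfoFitting:
    def test_noise_free_recovery_machine_tolerance(self, sfo_scenario):
        fit = ck.fit_sfo(ck.generate_trial(sfo_scenario))
        assert fit.converged
        assert fit.dt50_days == pytest.approx(2.0, abs=1e-6)
        assert fit.params.c0 == pytest.approx(10.0, rel=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.n_points == 7  # day -1 censored from the default schedule

    def test_monte_carlo_recovery_within_10pct(self):
        """Median recovered DT50 within 10% of truth at 15% CV, 200 seeds."""
        scenario = ck.TrialScenario(
            truth_params=ck.SfoParams(c0=10.0, k=LN2 / 2.0), cv_pct=15.0, seed=11
        )
        res = ck.recovery_study(scenario, 200, ck.fit_sfo)
        median = float(np.median(res.dt50_estimates))
        assert abs(median - 2.0) / 2.0 <= 0.10
        assert res.n_failed == 0

    def test_too_few_points_rejected(self, make=None):
        from conftest import make_series

        s = make_series([0, 1], [10.0, 5.0])
        with pytest.raises(ValueError, match="need >= 3"):
            ck.fit_sfo(s)

    def test_day0_required(self):
        from conftest import make_series

        s = make_series([1, 2, 3, 7], [5.0, 2.5, 1.2, 0.1])
        with pytest.raises(ValueError, match="day-0"):
            ck.fit_sfo(s)

    def test_estimator_api(self):
        t = np.array([0.0, 1, 2, 3, 7])
        y = 8.0 * np.exp(-0.4 * t)
        est = SFODeclineModel().fit(t.reshape(-1, 1), y)
        assert est.get_params() == {"log_space": False}
        assert est.k_ == pytest.approx(0.4, rel=1e-6)
        np.testing.assert_allclose(est.predict(t), y, rtol=1e-6)
        with pytest.raises(Exception):
            SFODeclineModel().predict(t)  # unfitted

    def test_log_space_flag_recovers_noise_free(self):
        t = np.array([0.0, 1, 2, 3, 7, 14])
        y = 5.0 * np.exp(-0.25 * t)
        est = SFODeclineModel(log_space=True).fit(t, y)
        assert est.dt50_ == pytest.approx(LN2 / 0.25, rel=1e-6)


class TestBiphasicFitting:
    def test_noise_free_recovery_4_significant_figures(self):
        truth = ck.BiphasicParams(c0=10.0, g=0.8, k1=LN2 / 0.5, k2=LN2 / 20.0)
        s = ck.TrialScenario(truth_params=truth, cv_pct=0.0, seed=3)
        fit = ck.fit_biphasic(ck.generate_trial(s))
        assert fit.converged and not fit.degenerate
        assert fit.params.c0 == pytest.approx(truth.c0, rel=1e-4)
        assert fit.params.g == pytest.approx(truth.g, rel=1e-4)
        assert fit.params.k1 == pytest.approx(truth.k1, rel=1e-4)
        assert fit.params.k2 == pytest.approx(truth.k2, rel=1e-4)

    def test_nests_sfo_on_single_phase_data(self, sfo_scenario):
        series = ck.generate_trial(sfo_scenario)
        sfo = ck.fit_sfo(series)
        bi = ck.fit_biphasic(series)
        # on pure SFO data the overall DT50 and the SFO DT50 coincide
        assert bi.dt50_days == pytest.approx(sfo.dt50_days, rel=1e-4)
        assert bi.rss <= sfo.rss + 1e-12

    def test_rss_ordering_on_noisy_fixtures(self):
        for seed in range(5):
            s = ck.TrialScenario(
                truth_params=ck.SfoParams(c0=10.0, k=LN2 / 3.0), cv_pct=20.0, seed=100 + seed
            )
            series = ck.generate_trial(s)
            assert ck.fit_biphasic(series).rss <= ck.fit_sfo(series).rss + 1e-10

    def test_too_few_points_rejected(self):
        from conftest import make_series

        s = make_series([0, 1, 2, 3], [10.0, 5.0, 2.6, 1.2])
        with pytest.raises(ValueError, match="need >= 5"):
            ck.fit_biphasic(s)

    def test_degenerate_flag_on_single_phase_data(self, sfo_scenario):
        fit = ck.fit_biphasic(ck.generate_trial(sfo_scenario))
        # g is free to sit at a boundary on single-phase data
        assert fit.degenerate or abs(fit.params.k1 - fit.params.k2) < 1e-6

    def test_estimator_normalizes_phase_order(self):
        t = np.linspace(0, 21, 8)
        p = ck.BiphasicParams(c0=4.0, g=0.3, k1=2.0, k2=0.05)
        est = BiphasicDeclineModel().fit(t, ck.biphasic_predict(p, t))
        assert est.k1_ >= est.k2_
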