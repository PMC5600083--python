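import math

import numpy as np
import pytest

from volbandit.agents import AgentSpec, simulate_agent
from volbandit.learning_rate import (
    EstimationWindow,
    choice_likelihood,
    condition_contrast,
    estimation_window,
    fit_learning_rate,
    fit_subject,
    predictor_trajectory,
)
from volbandit.schedule import ScheduleConfig, build_schedule

from conftest import make_schedule


class TestWindows:
    def test_short_windows_61_trials(self):
        ws = estimation_window("short", "stable")
        wv = estimation_window("short", "volatile")
        assert (ws.start, ws.end, ws.n_trials) == (20, 80, 61)
        assert (wv.start, wv.end, wv.n_trials) == (90, 150, 61)

    def test_long_windows_81_trials(self):
        ws = estimation_window("long", "stable")
        wv = estimation_window("long", "volatile")
        assert ws.n_trials == wv.n_trials == 81
        assert (ws.start, ws.end) == (40, 120)
        assert (wv.start, wv.end) == (210, 290)

    def test_long_volatile_first(self):
        ws = estimation_window("long", "stable", volatile_first=True)
        wv = estimation_window("long", "volatile", volatile_first=True)
        assert (wv.start, wv.end) == (90, 170)
        assert (ws.start, ws.end) == (210, 290)

    def test_window_outside_data_rejected(self):
        w = EstimationWindow("stable", 100, 200)
        with pytest.raises(ValueError):
            w.mask(160)


class TestPredictor:
    def test_matches_explicit_recursion(self, rng):
        y = rng.integers(0, 2, size=50).astype(float)
        alpha = 0.37
        r = 0.5
        expected = []
        for t in range(50):
            expected.append(r)
            r = r + alpha * (y[t] - r)
        assert np.allclose(predictor_trajectory(alpha, y), expected)


class TestChoiceLikelihood:
    def test_beta_zero_is_coin_flip(self, short_schedule):
        sched = short_schedule.with_choices(["A"] * 160)
        w = estimation_window("short", "stable")
        nll = choice_likelihood(0.3, 0.0, sched, w)
        assert nll == pytest.approx(61 * math.log(2), rel=1e-12)
        # and independent of alpha
        assert nll == pytest.approx(choice_likelihood(0.9, 0.0, sched, w))

    def test_matched_deterministic_agent_near_zero_nll(self, short_schedule):
        spec = AgentSpec("delta_rule", alpha=1.0, beta=1000.0, seed=1)
        sched = short_schedule.with_choices(simulate_agent(spec, short_schedule))
        w = estimation_window("short", "stable")
        nll = choice_likelihood(0.999, 50.0, sched, w)
        assert nll < 1.0  # near-deterministic and matched

    def test_five_trial_hand_worked_value(self):
        """Oracle: explicit by-hand arithmetic for a written-out 5-trial log."""
        rewarded = ["A", "B", "A", "A", "B"]
        mag_a = [30, 70, 50, 20, 90]
        choices = ["A", "A", "B", "A", "B"]
        sched = make_schedule(rewarded, mag_a, choices=choices)
        alpha, beta = 0.4, 0.1

        # hand loop, plain floats, magnitudes rescaled to [0, 1]
        def sigma(x):
            return 1.0 / (1.0 + math.exp(-x))

        r = 0.5
        nll_hand = 0.0
        y_seq = [1.0, 0.0, 1.0, 1.0, 0.0]
        for t in range(5):
            ma, mb = mag_a[t] / 100.0, (100 - mag_a[t]) / 100.0
            p_a = sigma(beta * (r * ma - (1.0 - r) * mb))
            p_choice = p_a if choices[t] == "A" else 1.0 - p_a
            nll_hand -= math.log(p_choice)
            r = r + alpha * (y_seq[t] - r)

        w = EstimationWindow("stable", 1, 5)
        assert choice_likelihood(alpha, beta, sched, w) == pytest.approx(nll_hand, rel=1e-12)

    def test_burn_in_updates_but_adds_no_terms(self, short_schedule):
        spec = AgentSpec("delta_rule", alpha=0.2, beta=5.0, seed=4)
        sched = short_schedule.with_choices(simulate_agent(spec, short_schedule))
        full = EstimationWindow("stable", 1, 80)
        windowed = EstimationWindow("stable", 20, 80)
        head = EstimationWindow("stable", 1, 19)
        nll_f = choice_likelihood(0.2, 5.0, sched, full)
        assert nll_f == pytest.approx(
            choice_likelihood(0.2, 5.0, sched, windowed)
            + choice_likelihood(0.2, 5.0, sched, head)
        )

    def test_domain_checks(self, short_schedule):
        sched = short_schedule.with_choices(["A"] * 160)
        w = estimation_window("short", "stable")
        with pytest.raises(ValueError):
            choice_likelihood(1.5, 1.0, sched, w)
        with pytest.raises(ValueError):
            choice_likelihood(0.5, -1.0, sched, w)


class TestFitLearningRate:
    def test_refit_bit_identical(self, short_schedule):
        spec = AgentSpec("delta_rule", alpha=0.25, beta=5.0, seed=8)
        sched = short_schedule.with_choices(simulate_agent(spec, short_schedule))
        w = estimation_window("short", "stable")
        a = fit_learning_rate(sched, w)
        b = fit_learning_rate(sched, w)
        assert a == b

    def test_recovers_alpha_rough(self):
        """Median alpha_hat across subjects lands near the generating value."""
        hats = []
        for seed in range(25):
            sched = build_schedule(ScheduleConfig("short", seed=seed))
            spec = AgentSpec("delta_rule", alpha=0.1, beta=5.0, seed=seed + 500)
            sched = sched.with_choices(simulate_agent(spec, sched))
            hats.append(fit_learning_rate(sched, estimation_window("short", "stable")).alpha_hat)
        assert 0.05 <= np.median(hats) <= 0.2

    def test_too_short_window_rejected(self, short_schedule):
        sched = short_schedule.with_choices(["A"] * 160)
        with pytest.raises(ValueError):
            fit_learning_rate(sched, EstimationWindow("stable", 1, 10))

    def test_log_alpha_consistent(self, short_schedule):
        spec = AgentSpec("delta_rule", alpha=0.25, beta=5.0, seed=8)
        sched = short_schedule.with_choices(simulate_agent(spec, short_schedule))
        fit = fit_learning_rate(sched, estimation_window("short", "stable"))
        assert fit.log_alpha == pytest.approx(math.log(fit.alpha_hat))

    def test_monotone_in_true_alpha(self):
        """Increasing the generating alpha increases the median estimate."""
        medians = []
        for alpha in (0.05, 0.2, 0.6):
            hats = []
            for seed in range(15):
                sched = build_schedule(ScheduleConfig("short", seed=seed))
                spec = AgentSpec("delta_rule", alpha=alpha, beta=5.0, seed=seed + 90)
                sched = sched.with_choices(simulate_agent(spec, sched))
                hats.append(
                    fit_learning_rate(sched, estimation_window("short", "volatile")).alpha_hat
                )
            medians.append(np.median(hats))
        assert medians[0] < medians[1] < medians[2]


class TestFitSubject:
    def test_shared_beta_forces_equal_betas(self, short_schedule):
        spec = AgentSpec("delta_rule", alpha=0.15, alpha_volatile=0.3, beta=5.0, seed=3)
        sched = short_schedule.with_choices(simulate_agent(spec, short_schedule))
        fits = fit_subject(sched, variant="short", shared_beta=True)
        assert fits["stable"].beta_hat == fits["volatile"].beta_hat

    def test_uses_schedule_config(self):
        sched = build_schedule(ScheduleConfig("short", seed=2))
        spec = AgentSpec("delta_rule", alpha=0.2, beta=5.0, seed=3)
        sched = sched.with_choices(simulate_agent(spec, sched))
        fits = fit_subject(sched)  # variant inferred from config
        assert fits["stable"].window.n_trials == 61


class TestConditionContrast:
    def _fits(self, la_s, la_v, converged=True):
        from volbandit.learning_rate import FitResult

        ws = estimation_window("short", "stable")
        wv = estimation_window("short", "volatile")
        return {
            "stable": FitResult(math.exp(la_s), 5.0, 10.0, ws, converged),
            "volatile": FitResult(math.exp(la_v), 5.0, 10.0, wv, True),
        }

    def test_identical_fits_zero_delta(self):
        res = condition_contrast({"s1": self._fits(-2.0, -2.0)})
        assert res["per_subject"]["s1"] == pytest.approx(0.0)

    def test_mean_and_ci(self):
        fits = {f"s{i}": self._fits(-2.0, -2.0 + d) for i, d in enumerate([0.5, 0.7, 0.9])}
        res = condition_contrast(fits)
        assert res["mean"] == pytest.approx(0.7)
        assert res["ci95"][0] < 0.7 < res["ci95"][1]

    def test_nonconverged_excluded(self):
        fits = {
            "good": self._fits(-2.0, -1.5),
            "bad": self._fits(-2.0, -1.0, converged=False),
        }
        with pytest.warns(UserWarning, match="excluded"):
            res = condition_contrast(fits)
        assert res["n"] == 1
        assert res["excluded"] == ["bad"]
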