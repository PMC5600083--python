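"""Windowed maximum-likelihood estimation of the delta-rule learning rate.

The model has a 'predictor' — a Rescorla-Wagner update of the estimated
reward probability for option A with a single learning rate ``alpha`` — and a
'selector' — a logistic choice rule on the expected-value difference with
inverse temperature ``beta``. ``beta`` is a jointly fitted nuisance
parameter.

The predictor runs from trial 1 (burn-in: trials before the estimation
window still update the estimate because the subject experienced them); only
trials inside the window contribute likelihood terms.

Estimation windows follow the task variants: for the short task the stable
window is trials 20-80 and the volatile window trials 90-150 (61 trials
each); for the long task each window is the last 81 trials of its phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .schedule import STABLE, VOLATILE, Schedule

__all__ = [
    "EstimationWindow",
    "FitResult",
    "estimation_window",
    "choice_likelihood",
    "fit_learning_rate",
    "fit_subject",
    "condition_contrast",
]

ALPHA_BOUNDS = (1e-3, 0.999)
BETA_BOUNDS = (0.0, 50.0)
PROB_FLOOR = 1e-10
# fixed 5x5 multi-start grid -> deterministic fits
ALPHA_STARTS = (0.05, 0.12, 0.25, 0.5, 0.8)
BETA_STARTS = (0.5, 2.0, 5.0, 10.0, 25.0)

SHORT_WINDOWS = {STABLE: (20, 80), VOLATILE: (90, 150)}
LONG_WINDOW_LEN = 81


@dataclass(frozen=True)
class EstimationWindow:
    """Inclusive 1-based trial window for one condition."""

    condition: str
    start: int
    end: int

    @property
    def n_trials(self) -> int:
        return self.end - self.start + 1

    def mask(self, n_total: int) -> np.ndarray:
        if not 1 <= self.start <= self.end <= n_total:
            raise ValueError(
                f"window [{self.start}, {self.end}] outside 1..{n_total}"
            )
        m = np.zeros(n_total, dtype=bool)
        m[self.start - 1 : self.end] = True
        return m


@dataclass(frozen=True)
class FitResult:
    alpha_hat: float
    beta_hat: float
    neg_log_likelihood: float
    window: EstimationWindow
    converged: bool

    @property
    def log_alpha(self) -> float:
        return float(np.log(self.alpha_hat))


def estimation_window(
    variant: str, condition: str, volatile_first: bool = False
) -> EstimationWindow:
    """Documented estimation window for a task variant and condition."""
    if condition not in (STABLE, VOLATILE):
        raise ValueError(f"condition must be stable/volatile, got {condition!r}")
    if variant == "short":
        start, end = SHORT_WINDOWS[condition]
        return EstimationWindow(condition, start, end)
    if variant == "long":
        # last 81 trials of each phase
        phases = [(VOLATILE, 170), (STABLE, 120)] if volatile_first else [(STABLE, 120), (VOLATILE, 170)]
        offset = 0
        for phase, length in phases:
            if phase == condition:
                return EstimationWindow(condition, offset + length - LONG_WINDOW_LEN + 1, offset + length)
            offset += length
    raise ValueError(f"no estimation window defined for variant {variant!r}")


def window_from_schedule(schedule: Schedule, condition: str) -> EstimationWindow:
    """Convenience: derive the window from a schedule's config."""
    cfg = schedule.config
    if cfg is None:
        raise ValueError("schedule has no config; pass an explicit window")
    return estimation_window(cfg.variant, condition, cfg.volatile_first)


def predictor_trajectory(alpha: float, outcomes: np.ndarray) -> np.ndarray:
    """Pre-choice delta-rule estimates r_hat[t] given outcome indicators.

    r_hat[0] = 0.5; r_hat[t] = r_hat[t-1] + alpha * (y[t-1] - r_hat[t-1]).
    Implemented as a first-order linear filter for speed.
    """
    y = np.asarray(outcomes, dtype=float)
    zi = np.array([(1.0 - alpha) * 0.5])
    filtered, _ = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], y, zi=zi)
    return np.concatenate(([0.5], filtered[:-1]))


class _SubjectArrays:
    """Pre-extracted numeric views of a choice-bearing schedule (hot path)."""

    def __init__(self, schedule: Schedule):
        choices = schedule.choices
        if choices is None:
            raise ValueError("schedule has no (complete) choice column")
        self.n = schedule.n_trials
        self.y = schedule.rewarded_a
        self.chose_a = choices > 0.5
        # selector operates on magnitudes rescaled to [0, 1]
        self.mag_a = schedule.magnitudes_a / 100.0
        self.mag_b = schedule.magnitudes_b / 100.0

    def nll(self, alpha: float, beta: float, mask: np.ndarray) -> float:
        r_hat = predictor_trajectory(alpha, self.y)
        ev_diff = r_hat * self.mag_a - (1.0 - r_hat) * self.mag_b
        p_a = 1.0 / (1.0 + np.exp(-beta * ev_diff))
        p_choice = np.where(self.chose_a, p_a, 1.0 - p_a)
        p_choice = np.clip(p_choice[mask], PROB_FLOOR, 1.0)
        return float(-np.log(p_choice).sum())


def choice_likelihood(
    alpha: float,
    beta: float,
    schedule: Schedule,
    window: EstimationWindow,
) -> float:
    """Negative log-likelihood of the windowed choices under (alpha, beta)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if beta < 0.0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    arrays = _SubjectArrays(schedule)
    return arrays.nll(alpha, beta, window.mask(schedule.n_trials))


def _polish_starts(objective, starts, bounds, n_polish: int = 5):
    """Rank the fixed start grid by objective value and polish the best few
    with bounded L-BFGS-B. Deterministic; returns (best result, any success).
    """
    ranked = sorted(starts, key=lambda s: objective(list(s)))
    best = None
    any_success = False
    for x0 in ranked[:n_polish]:
        res = optimize.minimize(
            objective, x0=list(x0), method="L-BFGS-B", bounds=bounds
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, any_success


def fit_learning_rate(
    schedule: Schedule,
    window: EstimationWindow,
    min_trials: int = 30,
) -> FitResult:
    """Bounded multi-start ML fit of (alpha, beta) for one window.

    Deterministic given the fixed start grid. ``converged`` is False when no
    start converges; such fits should be excluded downstream.
    """
    if window.n_trials < min_trials:
        raise ValueError(
            f"window has {window.n_trials} trials; need >= {min_trials}"
        )

    arrays = _SubjectArrays(schedule)
    mask = window.mask(schedule.n_trials)

    def objective(params):
        return arrays.nll(params[0], params[1], mask)

    best, any_success = _polish_starts(
        objective,
        [(a0, b0) for a0 in ALPHA_STARTS for b0 in BETA_STARTS],
        bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
    )
    if not any_success:
        warnings.warn("no optimizer start converged; flagging fit", RuntimeWarning)
    return FitResult(
        alpha_hat=float(best.x[0]),
        beta_hat=float(best.x[1]),
        neg_log_likelihood=float(best.fun),
        window=window,
        converged=any_success,
    )


def fit_subject(
    schedule: Schedule,
    variant: str | None = None,
    volatile_first: bool = False,
    shared_beta: bool = False,
) -> dict:
    """Fit both condition windows for one subject.

    With ``shared_beta`` a single selector temperature is optimized jointly
    across the two windows (3-parameter fit); otherwise each window gets its
    own (alpha, beta).
    """
    if variant is None:
        if schedule.config is None:
            raise ValueError("variant not given and schedule has no config")
        variant = schedule.config.variant
        volatile_first = schedule.config.volatile_first
    w_stable = estimation_window(variant, STABLE, volatile_first)
    w_vol = estimation_window(variant, VOLATILE, volatile_first)

    if not shared_beta:
        return {
            STABLE: fit_learning_rate(schedule, w_stable),
            VOLATILE: fit_learning_rate(schedule, w_vol),
        }

    arrays = _SubjectArrays(schedule)
    m_s = w_stable.mask(schedule.n_trials)
    m_v = w_vol.mask(schedule.n_trials)

    def objective(params):
        a_s, a_v, b = params
        return arrays.nll(a_s, b, m_s) + arrays.nll(a_v, b, m_v)

    best, any_success = _polish_starts(
        objective,
        [(a0, a0, b0) for a0 in ALPHA_STARTS for b0 in BETA_STARTS],
        bounds=[ALPHA_BOUNDS, ALPHA_BOUNDS, BETA_BOUNDS],
    )
    nll_s = choice_likelihood(best.x[0], best.x[2], schedule, w_stable)
    nll_v = choice_likelihood(best.x[1], best.x[2], schedule, w_vol)
    return {
        STABLE: FitResult(float(best.x[0]), float(best.x[2]), nll_s, w_stable, any_success),
        VOLATILE: FitResult(float(best.x[1]), float(best.x[2]), nll_v, w_vol, any_success),
    }


def condition_contrast(fits_per_subject: dict) -> dict:
    """Per-subject volatile-minus-stable log learning-rate differences.

    Parameters
    ----------
    fits_per_subject:
        Mapping ``subject -> {'stable': FitResult, 'volatile': FitResult}``.
        Subjects with a missing or non-converged window are excluded (with a
        warning).

    Returns a dict with per-subject deltas, the group mean and its
    t-based 95% confidence interval.
    """
    deltas = {}
    excluded = []
    for subject, fits in fits_per_subject.items():
        fs, fv = fits.get(STABLE), fits.get(VOLATILE)
        if fs is None or fv is None or not (fs.converged and fv.converged):
            excluded.append(subject)
            continue
        deltas[subject] = fv.log_alpha - fs.log_alpha
    if excluded:
        warnings.warn(f"excluded subjects with missing/failed fits: {excluded}")
    values = np.array(list(deltas.values()))
    n = len(values)
    mean = float(values.mean()) if n else float("nan")
    if n >= 2:
        sem = values.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
    else:
        ci = (float("nan"), float("nan"))
    return {
        "per_subject": deltas,
        "mean": mean,
        "ci95": (float(ci[0]), float(ci[1])),
        "n": n,
        "excluded": excluded,
    }
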