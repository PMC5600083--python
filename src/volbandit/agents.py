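"""Synthetic choice generators for the two-armed task.

Every downstream analysis is exercised on cohorts produced here, so each
simulated subject is written out together with its ground-truth parameters.

Agent kinds
-----------
``delta_rule``
    Rescorla-Wagner predictor ``r_hat += alpha * (y - r_hat)`` (``y`` = 1 when
    option A was rewarded) plus a logistic selector on the expected-value
    difference. ``alpha`` may differ between the stable and volatile phases
    (``alpha_volatile``), which is the phenomenon the learning-rate fitter is
    meant to recover.
``ideal_observer``
    Same selector, but the predictor is the Bayesian volatility filter's
    trial-wise E[r].
``wsls``
    Win-stay lose-shift: repeat the previous choice iff it was rewarded.
``alternator``
    Strictly alternates between the options.
``value_follower``
    Picks the option with the larger displayed magnitude.
``random``
    Fair coin.

The selector is ``P(A) = (1 - 2*eps) * sigmoid(beta * (EV_A - EV_B)) + eps``
with expected values computed on magnitudes rescaled to [0, 1], so ``beta``
has a conventional softmax scale (beta ~ 5 is moderately deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import special

from .ideal_observer import run_observer
from .schedule import (
    OPTION_A,
    OPTION_B,
    STABLE,
    VOLATILE,
    Schedule,
    ScheduleConfig,
    build_schedule,
    write_trials,
)

AGENT_KINDS = ("delta_rule", "ideal_observer", "wsls", "alternator", "value_follower", "random")


@dataclass(frozen=True)
class AgentSpec:
    """Parameters of one simulated subject."""

    kind: str
    alpha: float = 0.3
    alpha_volatile: float | None = None  # None -> same alpha in both phases
    beta: float = 5.0
    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; expected one of {AGENT_KINDS}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.alpha_volatile is not None and not 0.0 < self.alpha_volatile <= 1.0:
            raise ValueError(f"alpha_volatile must be in (0, 1], got {self.alpha_volatile}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in [0, 0.5), got {self.epsilon}")


def select_prob_a(r_hat, mag_a, mag_b, beta, epsilon=0.0):
    """Probability of choosing A from the logistic expected-value selector.

    Magnitudes are rescaled to [0, 1] inside the selector.
    """
    ev_diff = r_hat * np.asarray(mag_a) / 100.0 - (1.0 - r_hat) * np.asarray(mag_b) / 100.0
    p = special.expit(beta * ev_diff)
    return (1.0 - 2.0 * epsilon) * p + epsilon


def _phase_alphas(spec: AgentSpec, schedule: Schedule) -> np.ndarray:
    a_vol = spec.alpha_volatile if spec.alpha_volatile is not None else spec.alpha
    return np.where(schedule.conditions == VOLATILE, a_vol, spec.alpha)


def simulate_agent(spec: AgentSpec, schedule: Schedule) -> np.ndarray:
    """Simulate one choice per trial; returns an array of 'A'/'B' labels."""
    rng = np.random.default_rng(spec.seed)
    n = schedule.n_trials
    y = schedule.rewarded_a
    mag_a, mag_b = schedule.magnitudes_a, schedule.magnitudes_b

    if spec.kind == "random":
        chose_a = rng.random(n) < 0.5
    elif spec.kind == "value_follower":
        chose_a = mag_a > mag_b
        ties = mag_a == mag_b
        chose_a = np.where(ties, rng.random(n) < 0.5, chose_a)
    elif spec.kind == "alternator":
        first = rng.random() < 0.5
        chose_a = np.arange(n) % 2 == 0 if first else np.arange(n) % 2 == 1
    elif spec.kind == "wsls":
        chose_a = np.empty(n, dtype=bool)
        chose_a[0] = rng.random() < 0.5
        for t in range(1, n):
            won = chose_a[t - 1] == bool(y[t - 1])
            chose_a[t] = chose_a[t - 1] if won else not chose_a[t - 1]
    elif spec.kind == "ideal_observer":
        traj = run_observer(schedule)
        # predictive estimate: posterior before trial t's outcome
        r_hat = np.concatenate(([0.5], traj.e_r[:-1]))
        p = select_prob_a(r_hat, mag_a, mag_b, spec.beta, spec.epsilon)
        chose_a = rng.random(n) < p
    else:  # delta_rule
        alphas = _phase_alphas(spec, schedule)
        r_hat = np.empty(n)
        r = 0.5
        for t in range(n):
            r_hat[t] = r
            r = r + alphas[t] * (y[t] - r)
        p = select_prob_a(r_hat, mag_a, mag_b, spec.beta, spec.epsilon)
        chose_a = rng.random(n) < p

    return np.where(chose_a, OPTION_A, OPTION_B)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_DISTRIBUTIONS: dict[str, Callable] = {
    "fixed": lambda rng, v: float(v),
    "uniform": lambda rng, lo, hi: float(rng.uniform(lo, hi)),
    "loguniform": lambda rng, lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
    "normal": lambda rng, m, s: float(rng.normal(m, s)),
}


def _draw(dist, rng) -> float:
    """Draw from a distribution spec like {'fixed': 0.2} or {'uniform': [a, b]}."""
    if isinstance(dist, (int, float)):
        return float(dist)
    (name, params), = dist.items()
    if name not in _DISTRIBUTIONS:
        raise ValueError(f"unknown distribution {name!r}")
    params = params if isinstance(params, (list, tuple)) else [params]
    return _DISTRIBUTIONS[name](rng, *params)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    kind: str = "delta_rule"
    alpha_stable: object = field(default_factory=lambda: {"fixed": 0.2})
    alpha_volatile: object = None  # None -> same as stable draw
    beta: object = field(default_factory=lambda: {"fixed": 5.0})
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    schedule_config: ScheduleConfig
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        groups = tuple(GroupSpec(**g) for g in d["groups"])
        return cls(
            groups=groups,
            schedule_config=ScheduleConfig.from_dict(d["schedule"]),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SubjectData:
    subject: str
    group: str
    schedule: Schedule  # carries the subject's choices
    truth: dict


@dataclass
class Cohort:
    subjects: list

    def __len__(self) -> int:
        return len(self.subjects)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"subject": s.subject, "group": s.group, **s.truth} for s in self.subjects])


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate all groups; each subject gets its own schedule seed and agent seed.

    Ground-truth parameters are recorded per subject so parameter-recovery
    analyses are always possible on generated data.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = []
    idx = 0
    for group in spec.groups:
        for _ in range(group.n_subjects):
            idx += 1
            sched_seed = int(rng.integers(0, 2**31 - 1))
            agent_seed = int(rng.integers(0, 2**31 - 1))
            a_stable = _draw(group.alpha_stable, rng)
            a_vol = a_stable if group.alpha_volatile is None else _draw(group.alpha_volatile, rng)
            beta = _draw(group.beta, rng)
            sched = build_schedule(
                ScheduleConfig(**{**spec.schedule_config.to_dict(), "seed": sched_seed})
            )
            agent = AgentSpec(
                kind=group.kind,
                alpha=a_stable,
                alpha_volatile=a_vol,
                beta=beta,
                epsilon=group.epsilon,
                seed=agent_seed,
            )
            choices = simulate_agent(agent, sched)
            subjects.append(
                SubjectData(
                    subject=f"s{idx:03d}",
                    group=group.label,
                    schedule=sched.with_choices(choices),
                    truth={
                        "kind": group.kind,
                        "alpha_stable": a_stable,
                        "alpha_volatile": a_vol,
                        "beta": beta,
                        "epsilon": group.epsilon,
                        "schedule_seed": sched_seed,
                        "agent_seed": agent_seed,
                    },
                )
            )
    return Cohort(subjects)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write per-subject trial logs plus a ``truth.csv`` of generating parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_trials(s.schedule, out / f"{s.subject}.csv")
    cohort.truth_frame().to_csv(out / "truth.csv", index=False)


def read_cohort(in_dir) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    from .schedule import read_trials

    in_dir = Path(in_dir)
    truth = pd.read_csv(in_dir / "truth.csv")
    subjects = []
    for row in truth.to_dict("records"):
        sched = read_trials(in_dir / f"{row['subject']}.csv")
        subjects.append(
            SubjectData(
                subject=row.pop("subject"),
                group=str(row.pop("group")),
                schedule=sched,
                truth=row,
            )
        )
    return Cohort(subjects)
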