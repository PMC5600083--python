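"""Reward schedules for the two-armed "treasure chest" task.

The task presents two options (coded ``A`` and ``B``; ``A`` is the option most
often rewarded in the initial stable phase). Exactly one option is rewarded on
each trial, and the two displayed reward magnitudes always sum to 100 points.

Three schedule variants are supported:

* ``short`` — 80 stable trials at 75:25 followed by 80 volatile trials whose
  majority option flips every 20 trials (80:20 / 20:80).
* ``long`` — 120 stable trials at 75:25 and 170 volatile trials with a
  30-40-30-40-30 switch structure; phase order is configurable.
* ``familiarization`` — a single 20-trial block at 80:20.

Reward sides are realized with *exact* per-block ratios (a shuffled
deterministic count of A-rewards per block) rather than i.i.d. draws, so the
nominal ratios hold exactly at block scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

OPTION_A = "A"
OPTION_B = "B"
STABLE = "stable"
VOLATILE = "volatile"
MAGNITUDE_TOTAL = 100

TRIAL_COLUMNS = ["trial", "rewarded", "mag_a", "mag_b", "condition", "block", "choice"]


class ScheduleError(ValueError):
    """Invalid schedule configuration or trial-log contents."""


@dataclass(frozen=True)
class TrialRecord:
    """One task trial (1-based ``index``)."""

    index: int
    rewarded_option: str
    magnitude_a: int
    magnitude_b: int
    condition: str
    block_id: int
    choice: str | None = None

    def __post_init__(self) -> None:
        if self.rewarded_option not in (OPTION_A, OPTION_B):
            raise ScheduleError(
                f"trial {self.index}: rewarded_option must be 'A' or 'B', "
                f"got {self.rewarded_option!r}"
            )
        if self.magnitude_a + self.magnitude_b != MAGNITUDE_TOTAL:
            raise ScheduleError(
                f"trial {self.index}: magnitudes {self.magnitude_a}/{self.magnitude_b} "
                f"do not sum to {MAGNITUDE_TOTAL}"
            )
        if self.choice is not None and self.choice not in (OPTION_A, OPTION_B):
            raise ScheduleError(
                f"trial {self.index}: choice must be 'A', 'B' or None, got {self.choice!r}"
            )


@dataclass(frozen=True)
class Block:
    length: int
    p_a: float
    condition: str


@dataclass(frozen=True)
class ScheduleConfig:
    """Declarative description of a schedule variant.

    Parameters
    ----------
    variant:
        One of ``short``, ``long``, ``familiarization``.
    seed:
        Seed for magnitude draws and within-block reward placement.
    first_volatile_p_a:
        Majority side of the first volatile block. The default ``0.2``
        reverses the stable phase's majority option at the first switch.
    volatile_first:
        Long variant only: present the volatile phase before the stable one.
    """

    variant: str
    seed: int = 0
    first_volatile_p_a: float = 0.2
    volatile_first: bool = False

    VARIANTS = ("short", "long", "familiarization")

    def __post_init__(self) -> None:
        if self.variant not in self.VARIANTS:
            raise ScheduleError(
                f"unknown variant {self.variant!r}; expected one of {self.VARIANTS}"
            )
        if self.first_volatile_p_a not in (0.2, 0.8):
            raise ScheduleError("first_volatile_p_a must be 0.2 or 0.8")
        if self.volatile_first and self.variant != "long":
            raise ScheduleError("volatile_first is only meaningful for the long variant")

    def blocks(self) -> list[Block]:
        """Expand the variant into an ordered list of blocks."""
        p0 = self.first_volatile_p_a
        p1 = 1.0 - p0
        if self.variant == "short":
            vol = [Block(20, p, VOLATILE) for p in (p0, p1, p0, p1)]
            return [Block(80, 0.75, STABLE)] + vol
        if self.variant == "long":
            lengths = (30, 40, 30, 40, 30)
            vol = [
                Block(n, p0 if i % 2 == 0 else p1, VOLATILE)
                for i, n in enumerate(lengths)
            ]
            stable = [Block(120, 0.75, STABLE)]
            return vol + stable if self.volatile_first else stable + vol
        return [Block(20, 0.8, STABLE)]  # familiarization

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "seed": self.seed,
            "first_volatile_p_a": self.first_volatile_p_a,
            "volatile_first": self.volatile_first,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScheduleConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScheduleConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


@dataclass
class Schedule:
    """An ordered trial sequence plus block annotations and switch points."""

    trials: list[TrialRecord]
    switch_points: list[int]
    config: ScheduleConfig | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    # -- vectorized views ---------------------------------------------------
    @property
    def rewarded_a(self) -> np.ndarray:
        """Indicator array: 1 where option A was rewarded."""
        return np.array([t.rewarded_option == OPTION_A for t in self.trials], dtype=float)

    @property
    def magnitudes_a(self) -> np.ndarray:
        return np.array([t.magnitude_a for t in self.trials], dtype=float)

    @property
    def magnitudes_b(self) -> np.ndarray:
        return np.array([t.magnitude_b for t in self.trials], dtype=float)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([t.condition for t in self.trials])

    @property
    def choices(self) -> np.ndarray | None:
        """Choice indicator (1 = chose A) or None if any choice is missing."""
        if any(t.choice is None for t in self.trials):
            return None
        return np.array([t.choice == OPTION_A for t in self.trials], dtype=float)

    def condition_trials(self, condition: str) -> np.ndarray:
        """1-based trial indices belonging to ``condition``."""
        return np.array([t.index for t in self.trials if t.condition == condition])

    def with_choices(self, choices: Sequence[str] | np.ndarray) -> "Schedule":
        """Return a copy with a choice attached to every trial.

        Accepts either 'A'/'B' labels or a 0/1 array (1 = A).
        """
        if len(choices) != self.n_trials:
            raise ScheduleError(
                f"{len(choices)} choices for {self.n_trials} trials"
            )
        labels = [
            c if isinstance(c, str) else (OPTION_A if c else OPTION_B) for c in choices
        ]
        trials = [replace(t, choice=c) for t, c in zip(self.trials, labels)]
        return Schedule(trials, list(self.switch_points), self.config)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "rewarded": [t.rewarded_option for t in self.trials],
                "mag_a": [t.magnitude_a for t in self.trials],
                "mag_b": [t.magnitude_b for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "block": [t.block_id for t in self.trials],
                "choice": [t.choice if t.choice is not None else "NA" for t in self.trials],
            }
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_schedule(config: ScheduleConfig) -> Schedule:
    """Generate a schedule from a config; deterministic given ``config.seed``.

    Per block of length ``L`` with A-reward probability ``p``, exactly
    ``round(L * p)`` trials (half-up) reward A, placed uniformly at random
    within the block. Magnitudes are independent uniform integers in
    [0, 100] for A, with B taking the complement to 100.
    """
    rng = np.random.default_rng(config.seed)
    blocks = config.blocks()
    trials: list[TrialRecord] = []
    switch_points: list[int] = []
    index = 0
    prev_p = None
    for block_id, block in enumerate(blocks, start=1):
        if block.length < 1:
            raise ScheduleError(f"block {block_id} has length {block.length}")
        if not 0.0 < block.p_a < 1.0:
            raise ScheduleError(f"block {block_id} has p_a {block.p_a} outside (0, 1)")
        if prev_p is not None and block.p_a != prev_p:
            switch_points.append(index + 1)
        prev_p = block.p_a
        n_a = _round_half_up(block.length * block.p_a)
        rewards = np.zeros(block.length, dtype=bool)
        rewards[:n_a] = True
        rng.shuffle(rewards)
        mags = rng.integers(0, MAGNITUDE_TOTAL + 1, size=block.length)
        for rewarded, mag_a in zip(rewards, mags):
            index += 1
            trials.append(
                TrialRecord(
                    index=index,
                    rewarded_option=OPTION_A if rewarded else OPTION_B,
                    magnitude_a=int(mag_a),
                    magnitude_b=MAGNITUDE_TOTAL - int(mag_a),
                    condition=block.condition,
                    block_id=block_id,
                )
            )
    return Schedule(trials=trials, switch_points=switch_points, config=config)


def write_trials(schedule: Schedule, path: str | Path) -> None:
    """Write a trial log as CSV (columns: trial,rewarded,mag_a,mag_b,condition,block,choice)."""
    schedule.to_frame().to_csv(path, index=False)


def read_trials(path: str | Path) -> Schedule:
    """Read a trial log written by :func:`write_trials`; validates invariants.

    The ``choice`` column is optional; 'NA' / missing entries yield trials
    without choices.
    """
    df = pd.read_csv(path, dtype={"rewarded": str, "condition": str})
    required = {"trial", "rewarded", "mag_a", "mag_b", "condition", "block"}
    missing = required - set(df.columns)
    if missing:
        raise ScheduleError(f"missing required column(s): {sorted(missing)}")
    return schedule_from_frame(df)


def schedule_from_frame(df: pd.DataFrame) -> Schedule:
    bad = df.loc[df["mag_a"] + df["mag_b"] != MAGNITUDE_TOTAL, "trial"]
    if len(bad):
        raise ScheduleError(
            f"magnitudes do not sum to {MAGNITUDE_TOTAL} on trial(s): {bad.tolist()}"
        )
    dup = df.loc[df["trial"].duplicated(), "trial"]
    if len(dup):
        raise ScheduleError(f"duplicate trial index(es): {sorted(set(dup.tolist()))}")

    has_choice = "choice" in df.columns
    trials = []
    for row in df.itertuples(index=False):
        choice = None
        if has_choice:
            raw = getattr(row, "choice")
            if isinstance(raw, str) and raw in (OPTION_A, OPTION_B):
                choice = raw
        trials.append(
            TrialRecord(
                index=int(row.trial),
                rewarded_option=str(row.rewarded),
                magnitude_a=int(row.mag_a),
                magnitude_b=int(row.mag_b),
                condition=str(row.condition),
                block_id=int(row.block),
                choice=choice,
            )
        )
    trials.sort(key=lambda t: t.index)
    switch_points = _infer_switch_points(trials)
    return Schedule(trials=trials, switch_points=switch_points)


def _infer_switch_points(trials: list[TrialRecord]) -> list[int]:
    """Recover switch points from block boundaries (block id changes)."""
    points = []
    for prev, cur in zip(trials, trials[1:]):
        if cur.block_id != prev.block_id:
            points.append(cur.index)
    return points
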