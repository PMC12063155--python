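"""Structure of the 2x2 effort x reward probabilistic learning task.

Participants learn which of two pseudo-word spellings in a pair is correct
from probabilistic feedback (the correct spelling is rewarded on 80% of
choices, the incorrect one on 20%). Effort is manipulated by the number of
pairs learned in parallel (2 vs 4) and reward by the points at stake
(1 vs 10 per correct choice). Each pair is shown 16 times, so low-effort
runs have 32 trials and high-effort runs 64; a subject completes one run
per condition, 192 trials in total.

This module builds seeded, fully reproducible run schedules (pair order,
left/right counterbalancing, fixation jitters, event onsets) and the
feedback schedule that determines, per trial, whether choosing the
correct / incorrect option would be rewarded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "Condition",
    "RunSchedule",
    "CONDITIONS",
    "build_run_schedule",
    "draw_feedback_schedule",
    "counterbalance_orders",
    "schedule_table",
    "save_task_config",
    "load_task_config",
]

#: Allowed fixation-jitter values in seconds (2-4 s in 0.5 s steps).
JITTER_GRID = (2.0, 2.5, 3.0, 3.5, 4.0)

LEVELS = ("low", "high")
_CODE = {"low": -1, "high": 1}


class ConfigurationError(ValueError):
    """Raised for invalid task configuration or condition levels."""


@dataclass(frozen=True)
class TaskConfig:
    """Design constants of the learning task.

    ``exact_frequency_feedback`` switches the feedback schedule from
    independent Bernoulli draws per trial (the default) to permuted
    schedules with a fixed number of rewarded trials per pair. With 16
    repetitions an exact 80% is impossible (12.8 trials), so the permuted
    variant rounds to 13/16 (~81%); i.i.d. draws are therefore the default.
    """

    pairs_low_effort: int = 2
    pairs_high_effort: int = 4
    reps_per_pair: int = 16
    points_low_reward: int = 1
    points_high_reward: int = 10
    p_reward_correct: float = 0.80
    p_reward_incorrect: float = 0.20
    jitter_grid: Sequence[float] = JITTER_GRID
    stimulus_duration: float = 2.0
    frame_duration: float = 0.5
    response_deadline: float = 2.0
    feedback_duration: float = 1.0
    euro_per_point: float = 0.10
    missed_rate: float = 0.011
    exact_frequency_feedback: bool = False

    def __post_init__(self) -> None:
        for name in ("pairs_low_effort", "pairs_high_effort", "reps_per_pair"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("p_reward_correct", "p_reward_incorrect", "missed_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if abs(self.p_reward_correct + self.p_reward_incorrect - 1.0) > 1e-12:
            raise ConfigurationError(
                "reward probabilities of the two spellings must sum to 1"
            )

    def n_pairs(self, effort_level: str) -> int:
        if effort_level == "low":
            return self.pairs_low_effort
        if effort_level == "high":
            return self.pairs_high_effort
        raise ConfigurationError(f"unknown effort level {effort_level!r}")

    def points(self, reward_level: str) -> int:
        if reward_level == "low":
            return self.points_low_reward
        if reward_level == "high":
            return self.points_high_reward
        raise ConfigurationError(f"unknown reward level {reward_level!r}")


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2 design with its -1/+1 contrast codes."""

    effort: str
    reward: str

    def __post_init__(self) -> None:
        if self.effort not in LEVELS or self.reward not in LEVELS:
            raise ConfigurationError(
                f"condition levels must be in {LEVELS}, got "
                f"effort={self.effort!r} reward={self.reward!r}"
            )

    @property
    def effort_code(self) -> int:
        return _CODE[self.effort]

    @property
    def reward_code(self) -> int:
        return _CODE[self.reward]


#: Canonical condition order used by the Latin-square counterbalancing.
CONDITIONS = (
    Condition("low", "low"),
    Condition("low", "high"),
    Condition("high", "low"),
    Condition("high", "high"),
)


@dataclass
class RunSchedule:
    """A single run: its condition and the ordered trial slots.

    ``trials`` columns: trial_index, pair_id, correct_side, jitter1_s,
    jitter2_s, stim_onset_s, feedback_onset_s.
    """

    condition: Condition
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_s(self) -> float:
        """Run-relative time at which the last feedback event ends."""
        return float(self.trials["feedback_onset_s"].iloc[-1])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_run_schedule(condition: Condition, config: TaskConfig, seed) -> RunSchedule:
    """Generate one seeded run schedule.

    Pair order is a uniformly random interleaving subject to each pair
    appearing exactly ``reps_per_pair`` times; the correct option appears
    on the left for exactly half of each pair's presentations; both
    fixation jitters are drawn uniformly from the jitter grid. Onsets are
    run-relative seconds: each trial is jitter1 -> stimulus (2 s, choice
    window) -> selection frame (0.5 s) -> jitter2 -> feedback.
    """
    rng = _as_rng(seed)
    n_pairs = config.n_pairs(condition.effort)
    reps = config.reps_per_pair

    pair_ids = rng.permutation(np.repeat(np.arange(n_pairs), reps))

    # 8 left / 8 right per pair, in random within-pair order
    correct_side = np.empty(len(pair_ids), dtype=object)
    for p in range(n_pairs):
        sides = np.array(["left"] * (reps // 2) + ["right"] * (reps - reps // 2))
        correct_side[pair_ids == p] = rng.permutation(sides)

    grid = np.asarray(config.jitter_grid, dtype=float)
    jitter1 = rng.choice(grid, size=len(pair_ids))
    jitter2 = rng.choice(grid, size=len(pair_ids))

    stim_onset = np.empty(len(pair_ids))
    feedback_onset = np.empty(len(pair_ids))
    t = 0.0
    for i in range(len(pair_ids)):
        stim_onset[i] = t + jitter1[i]
        feedback_onset[i] = (
            stim_onset[i] + config.stimulus_duration + config.frame_duration + jitter2[i]
        )
        t = feedback_onset[i] + config.feedback_duration

    trials = pd.DataFrame(
        {
            "trial_index": np.arange(len(pair_ids)),
            "pair_id": pair_ids.astype(int),
            "correct_side": correct_side,
            "jitter1_s": jitter1,
            "jitter2_s": jitter2,
            "stim_onset_s": stim_onset,
            "feedback_onset_s": feedback_onset,
        }
    )
    return RunSchedule(condition=condition, trials=trials)


def draw_feedback_schedule(
    schedule: RunSchedule, config: TaskConfig, rng
) -> pd.DataFrame:
    """Pre-draw, per trial, whether each spelling would be rewarded.

    Returns the schedule's trial table with two extra columns,
    ``reward_if_correct`` and ``reward_if_incorrect`` (0/1). By default
    both are i.i.d. Bernoulli (0.80 / 0.20); with
    ``config.exact_frequency_feedback`` the counts per pair are fixed at
    round(p * reps) and permuted.
    """
    rng = _as_rng(rng)
    trials = schedule.trials.copy()
    n = len(trials)
    if config.exact_frequency_feedback:
        r_cor = np.empty(n, dtype=int)
        r_inc = np.empty(n, dtype=int)
        for p in trials["pair_id"].unique():
            mask = (trials["pair_id"] == p).to_numpy()
            reps = int(mask.sum())
            n_cor = int(round(config.p_reward_correct * reps))
            n_inc = int(round(config.p_reward_incorrect * reps))
            vec_c = np.zeros(reps, dtype=int)
            vec_c[:n_cor] = 1
            vec_i = np.zeros(reps, dtype=int)
            vec_i[:n_inc] = 1
            r_cor[mask] = rng.permutation(vec_c)
            r_inc[mask] = rng.permutation(vec_i)
    else:
        r_cor = (rng.random(n) < config.p_reward_correct).astype(int)
        r_inc = (rng.random(n) < config.p_reward_incorrect).astype(int)
    trials["reward_if_correct"] = r_cor
    trials["reward_if_incorrect"] = r_inc
    return trials


def counterbalance_orders(n_subjects: int) -> pd.DataFrame:
    """Per-subject condition orders from a cyclic 4x4 Latin square.

    Subject ``s`` receives row ``s % 4``; with n a multiple of 4 every
    condition occupies every run position equally often.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rows = []
    for s in range(n_subjects):
        for run in range(4):
            cond = CONDITIONS[(s + run) % 4]
            rows.append(
                {
                    "subject": s,
                    "run_index": run,
                    "effort_level": cond.effort,
                    "reward_level": cond.reward,
                }
            )
    return pd.DataFrame(rows)


def schedule_table(subject: int, run_index: int, schedule: RunSchedule) -> pd.DataFrame:
    """Flatten a RunSchedule into the serializable per-trial table."""
    out = schedule.trials.copy()
    out.insert(0, "subject", subject)
    out.insert(1, "run_index", run_index)
    out.insert(2, "effort_level", schedule.condition.effort)
    out.insert(3, "reward_level", schedule.condition.reward)
    return out


_CONFIG_TYPES = {f.name: f.type for f in dataclasses.fields(TaskConfig)}


def save_task_config(config: TaskConfig, path) -> None:
    """Write the config as flat ``key = value`` text."""
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, (tuple, list)):
            value = ",".join(str(v) for v in value)
        lines.append(f"{f.name} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_task_config(path) -> TaskConfig:
    """Read a config written by :func:`save_task_config`."""
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key == "jitter_grid":
            kwargs[key] = tuple(float(v) for v in raw.split(","))
        elif key == "exact_frequency_feedback":
            kwargs[key] = raw.lower() in ("true", "1", "yes")
        elif key in ("pairs_low_effort", "pairs_high_effort", "reps_per_pair",
                     "points_low_reward", "points_high_reward"):
            kwargs[key] = int(raw)
        else:
            kwargs[key] = float(raw)
    return TaskConfig(**kwargs)
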