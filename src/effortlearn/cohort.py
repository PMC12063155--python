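"""Synthetic cohorts with known ground truth.

Generates everything the analysis pipeline consumes: Rescorla-Wagner
agents with age- and condition-structured parameters playing the 2x2
effort x reward task on counterbalanced schedules, discounting choices
driven by a true subjective value of effort, and ROI beta tables with a
specified reward x effort x age effect structure plus Gaussian noise.

Defaults mirror the study conditions the analyses assume: 146 subjects
aged 13-25, four runs of 32/64 trials on 80/20 contingencies, ~1.1%
missed trials, and a model-preferred-without-age regime (zero age
coefficients). ROI effect sizes are illustrative — chosen to produce the
qualitative reward x effort (x age) pattern, not estimates of any real
effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import discounting, rw, task

__all__ = [
    "PopulationSpec",
    "Cohort",
    "draw_agent",
    "simulate_subject",
    "simulate_discounting",
    "simulate_roi_betas",
    "generate_cohort",
    "DEFAULT_ROI_EFFECTS",
]

#: Illustrative generative effects per ROI (beta units): intercept plus
#: coefficients on the reward code, effort code, their product, and the
#: product with standardized age.
DEFAULT_ROI_EFFECTS: dict[str, dict[str, float]] = {
    "dACC": {"intercept": 1.0, "reward": 0.30, "effort": 0.10,
             "reward_effort": 0.30, "reward_effort_age": -0.15},
    "vmPFC": {"intercept": 0.8, "reward": 0.20, "effort": 0.0,
              "reward_effort": 0.0, "reward_effort_age": 0.0},
    "striatum_R": {"intercept": 1.2, "reward": 0.25, "effort": 0.0,
                   "reward_effort": 0.0, "reward_effort_age": 0.0},
    "striatum_L": {"intercept": 1.2, "reward": 0.25, "effort": 0.0,
                   "reward_effort": 0.0, "reward_effort_age": 0.0},
}

_COEF_KEYS = ("a_effort", "a_reward", "a_age", "b_effort", "b_reward", "b_age")


def _default_coef_means() -> dict[str, float]:
    return {"a_effort": -0.30, "a_reward": 0.30, "a_age": 0.0,
            "b_effort": -0.20, "b_reward": 0.20, "b_age": 0.0}


def _default_coef_sds() -> dict[str, float]:
    return {"a_effort": 0.30, "a_reward": 0.30, "a_age": 0.0,
            "b_effort": 0.30, "b_reward": 0.30, "b_age": 0.0}


@dataclass
class PopulationSpec:
    """Generative population the synthetic cohort is drawn from.

    Baseline learning rate and inverse temperature are Gaussian on their
    link scales (logit / log); condition and age coefficients are
    Gaussian with the stated means and dispersions. True subjective
    values are truncated-Gaussian euros on (0, 2); discounting choices
    are a softmax of (offer - true SV) with temperature
    ``sv_choice_noise``.
    """

    n_subjects: int = 146
    age_min: float = 13.0
    age_max: float = 25.0
    alpha_base_mean: float = -1.0   # logistic(-1.0) ~ 0.27
    alpha_base_sd: float = 0.8
    beta_base_mean: float = 1.6     # exp(1.6) ~ 5
    beta_base_sd: float = 0.5
    coef_means: Mapping[str, float] = field(default_factory=_default_coef_means)
    coef_sds: Mapping[str, float] = field(default_factory=_default_coef_sds)
    sv_mean: float = 1.0
    sv_sd: float = 0.4
    sv_choice_noise: float = 0.10
    roi_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ROI_EFFECTS.items()}
    )
    roi_noise_sd: float = 1.0
    missed_rate: float = 0.011

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.alpha_base_sd < 0 or self.beta_base_sd < 0 or self.roi_noise_sd < 0:
            raise ValueError("dispersions must be non-negative")
        for k in _COEF_KEYS:
            if self.coef_sds.get(k, 0.0) < 0:
                raise ValueError(f"coef_sds[{k!r}] must be non-negative")


def draw_agent(spec: PopulationSpec, rng: np.random.Generator) -> tuple[float, rw.AgentParams]:
    """Draw one subject's age and true link-scale parameters."""
    age = float(rng.uniform(spec.age_min, spec.age_max))
    coefs = {
        k: float(spec.coef_means.get(k, 0.0) + spec.coef_sds.get(k, 0.0) * rng.standard_normal())
        for k in _COEF_KEYS
    }
    params = rw.AgentParams(
        alpha_base=float(spec.alpha_base_mean + spec.alpha_base_sd * rng.standard_normal()),
        beta_base=float(spec.beta_base_mean + spec.beta_base_sd * rng.standard_normal()),
        a_effort=coefs["a_effort"],
        a_reward=coefs["a_reward"],
        b_effort=coefs["b_effort"],
        b_reward=coefs["b_reward"],
        a_age=coefs["a_age"],
        b_age=coefs["b_age"],
    )
    return age, params


def simulate_subject(
    agent: rw.AgentParams,
    schedules: list[tuple[int, task.RunSchedule]],
    config: task.TaskConfig,
    rng: np.random.Generator,
    age_z: float = 0.0,
    subject=0,
) -> pd.DataFrame:
    """Simulate a subject's four runs on pre-built schedules.

    Feedback availability is pre-drawn per trial for both spellings,
    each trial is independently missed with ``config.missed_rate``
    (missed trials carry no choice and trigger no value update), and
    choices come from the softmax forward pass of the learning model.
    """
    frames = []
    for run_index, schedule in schedules:
        trials = task.draw_feedback_schedule(schedule, config, rng)
        trials.insert(0, "subject", subject)
        trials.insert(1, "run_index", run_index)
        trials.insert(2, "effort_level", schedule.condition.effort)
        trials.insert(3, "reward_level", schedule.condition.reward)
        trials["missed"] = rng.random(len(trials)) < config.missed_rate
        frames.append(trials)
    all_trials = pd.concat(frames, ignore_index=True)
    sim = rw.simulate_choices(agent, all_trials, rng, age_z=age_z)
    points = np.where(
        sim["reward_level"] == "high", config.points_high_reward, config.points_low_reward
    )
    sim["points"] = sim["rewarded"] * points
    return sim


def simulate_discounting(
    true_sv: float, noise: float, rng: np.random.Generator
) -> Callable[[float], str]:
    """A discounting chooser driven by the true subjective value.

    Picks the low-effort option with probability
    logistic((offer - true_sv) / noise); at ``noise = 0`` this is a
    deterministic threshold rule (low-effort iff offer > true SV).
    """
    if not 0.0 < true_sv < 2.0:
        raise ValueError("true_sv must lie in (0, 2)")

    def chooser(offer: float) -> str:
        if noise <= 0.0:
            return "low_effort" if offer > true_sv else "high_effort"
        p_low = expit((offer - true_sv) / noise)
        return "low_effort" if rng.random() < p_low else "high_effort"

    return chooser


def simulate_roi_betas(
    spec: PopulationSpec, subjects: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """One beta per subject x condition x ROI with the spec's effect structure."""
    rows = []
    for _, subj in subjects.iterrows():
        for cond in task.CONDITIONS:
            e, r = cond.effort_code, cond.reward_code
            for roi, eff in spec.roi_effects.items():
                mean = (
                    eff.get("intercept", 0.0)
                    + eff.get("reward", 0.0) * r
                    + eff.get("effort", 0.0) * e
                    + eff.get("reward_effort", 0.0) * r * e
                    + eff.get("reward_effort_age", 0.0) * r * e * subj["age_z"]
                )
                rows.append(
                    {
                        "subject": subj["subject"],
                        "effort_level": cond.effort,
                        "reward_level": cond.reward,
                        "roi": roi,
                        "beta": mean + spec.roi_noise_sd * rng.standard_normal(),
                        "age": subj["age"],
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """A generated cohort: per-subject truth, trials, discounting, ROI betas."""

    spec: PopulationSpec
    seed: int
    subjects: pd.DataFrame
    trials: pd.DataFrame
    discounting: pd.DataFrame
    roi_betas: pd.DataFrame

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(directory / "subjects.tsv", sep="\t", index=False)
        self.trials.to_csv(directory / "trials.tsv", sep="\t", index=False)
        self.discounting.to_csv(directory / "discounting.tsv", sep="\t", index=False)
        self.roi_betas.to_csv(directory / "roi_betas.tsv", sep="\t", index=False)


def generate_cohort(
    spec: PopulationSpec,
    seed: int,
    config: task.TaskConfig | None = None,
) -> Cohort:
    """Generate a fully determined cohort from one integer seed.

    Ages and true parameters are drawn first; age is standardized with
    the cohort's own mean and SD before entering the generative link
    functions, mirroring how the analyses standardize covariates.
    Run orders follow the cyclic Latin square; each subject gets an
    independent random stream so regeneration is bit-identical.
    """
    config = config or task.TaskConfig(missed_rate=spec.missed_rate)
    root = np.random.SeedSequence(seed)
    master = np.random.default_rng(root.spawn(1)[0])
    n = spec.n_subjects

    ages, params_list = [], []
    for _ in range(n):
        age, params = draw_agent(spec, master)
        ages.append(age)
        params_list.append(params)
    ages = np.asarray(ages)
    age_sd = ages.std() if ages.std() > 0 else 1.0
    age_z = (ages - ages.mean()) / age_sd

    true_sv = np.clip(
        spec.sv_mean + spec.sv_sd * master.standard_normal(n), 0.01, 1.99
    )

    subjects = pd.DataFrame(
        {
            "subject": np.arange(n),
            "age": ages,
            "age_z": age_z,
            "true_sv": true_sv,
        }
    )
    for name in ("alpha_base", "beta_base", "a_effort", "a_reward",
                 "b_effort", "b_reward", "a_age", "b_age"):
        subjects[f"true_{name}"] = [getattr(p, name) for p in params_list]

    orders = task.counterbalance_orders(n)

    trial_frames, disc_rows, sv_rows = [], [], []
    subject_seeds = root.spawn(n)
    for s in range(n):
        rng = np.random.default_rng(subject_seeds[s])
        subj_orders = orders[orders["subject"] == s]
        schedules = []
        for _, row in subj_orders.iterrows():
            cond = task.Condition(row["effort_level"], row["reward_level"])
            schedules.append(
                (int(row["run_index"]), task.build_run_schedule(cond, config, rng))
            )
        trial_frames.append(
            simulate_subject(
                params_list[s], schedules, config, rng, age_z=age_z[s], subject=s
            )
        )
        chooser = simulate_discounting(float(true_sv[s]), spec.sv_choice_noise, rng)
        result = discounting.run_staircase(chooser)
        sv_rows.append({"subject": s, "sv": result.sv})
        for t, (offer, choice) in enumerate(result.history, start=1):
            disc_rows.append({"subject": s, "trial": t, "offer": offer, "choice": choice})

    sv_table = pd.DataFrame(sv_rows)
    if n >= 2:
        sv_table = discounting.assign_sv_groups(sv_table)
    else:
        sv_table["sv_group"] = "low"
        sv_table["sv_code"] = -1
    subjects = subjects.merge(sv_table, on="subject")

    roi_rng = np.random.default_rng(root.spawn(1)[0])
    roi_betas = simulate_roi_betas(spec, subjects, roi_rng)
    roi_betas = roi_betas.merge(subjects[["subject", "sv_group"]], on="subject")

    return Cohort(
        spec=spec,
        seed=seed,
        subjects=subjects,
        trials=pd.concat(trial_frames, ignore_index=True),
        discounting=pd.DataFrame(disc_rows),
        roi_betas=roi_betas,
    )
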