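"""Extended Rescorla-Wagner model with condition-linked parameters.

The agent tracks an expected value V for each spelling of each pair,
initialized equal (0.5) at the start of every run, and updates the chosen
option's value by the prediction error delta = r - V scaled by the
learning rate alpha. Choices follow a two-option softmax on the value
difference with inverse temperature beta. Outcomes are coded 0/1
(rewarded vs not) in all conditions, so V stays in [0, 1] and delta in
[-1, 1]; reward magnitude enters only through the condition regression
of the parameters.

Parameters live on link scales and are regressed on the -1/+1 effort and
reward contrast codes (optionally standardized age):

    alpha = logistic(alpha_base + a_effort*E + a_reward*R [+ a_age*z])
    beta  = exp(beta_base + b_effort*E + b_reward*R [+ b_age*z])

so each run has its own (alpha, beta) derived from one shared parameter
vector per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .task import Condition

__all__ = [
    "AgentParams",
    "LINK_CLAMP",
    "V0",
    "link_parameters",
    "update_value",
    "choice_probability",
    "negative_log_likelihood",
    "compute_trajectories",
    "simulate_choices",
    "trajectory_events_table",
]

#: Link-scale inputs are clamped to +-LINK_CLAMP before the inverse link.
LINK_CLAMP = 30.0

#: Initial expected value of both spellings in every pair.
V0 = 0.5


class LikelihoodError(FloatingPointError):
    """Raised when the likelihood evaluates to a non-finite number."""


@dataclass(frozen=True)
class AgentParams:
    """Link-scale parameters of the condition-regressed model.

    ``a_*`` act on the logit of the learning rate, ``b_*`` on the log of
    the inverse temperature. ``a_age``/``b_age`` are present (not None)
    only in the with-age model variant.
    """

    alpha_base: float = 0.0
    beta_base: float = 0.0
    a_effort: float = 0.0
    a_reward: float = 0.0
    b_effort: float = 0.0
    b_reward: float = 0.0
    a_age: Optional[float] = None
    b_age: Optional[float] = None

    @property
    def has_age(self) -> bool:
        return self.a_age is not None or self.b_age is not None


def _clamp(x: float) -> float:
    return float(np.clip(x, -LINK_CLAMP, LINK_CLAMP))


def link_parameters(
    params: AgentParams, condition: Condition, age_z: float = 0.0
) -> tuple[float, float]:
    """Map link-scale parameters to this condition's (alpha, beta)."""
    e, r = condition.effort_code, condition.reward_code
    eta_a = params.alpha_base + params.a_effort * e + params.a_reward * r
    eta_b = params.beta_base + params.b_effort * e + params.b_reward * r
    if params.a_age is not None:
        eta_a += params.a_age * age_z
    if params.b_age is not None:
        eta_b += params.b_age * age_z
    alpha = float(expit(_clamp(eta_a)))
    beta = float(np.exp(_clamp(eta_b)))
    return alpha, beta


def update_value(v: float, outcome: float, alpha: float) -> tuple[float, float]:
    """Delta-rule update of the chosen option: returns (V_new, delta)."""
    delta = outcome - v
    return v + alpha * delta, delta


def choice_probability(v_correct: float, v_incorrect: float, beta: float) -> float:
    """Softmax probability of choosing the correct spelling."""
    return float(expit(beta * (v_correct - v_incorrect)))


@njit(cache=False)
def _log_logistic(z):
    # log(sigmoid(z)), numerically stable
    if z >= 0.0:
        return -np.log1p(np.exp(-z))
    return z - np.log1p(np.exp(z))


@njit(cache=False)
def _run_nll(pair, chose_correct, rewarded, missed, alpha, beta, n_pairs, v0):
    """Negative log-likelihood of one run's choice sequence."""
    v_cor = np.full(n_pairs, v0)
    v_inc = np.full(n_pairs, v0)
    nll = 0.0
    for t in range(pair.shape[0]):
        if missed[t]:
            continue
        p = pair[t]
        dv = v_cor[p] - v_inc[p]
        z = beta * dv
        if chose_correct[t] == 1:
            nll -= _log_logistic(z)
            v_cor[p] += alpha * (rewarded[t] - v_cor[p])
        else:
            nll -= _log_logistic(-z)
            v_inc[p] += alpha * (rewarded[t] - v_inc[p])
    return nll


@njit(cache=False)
def _run_traj(pair, chose_correct, rewarded, missed, alpha, beta, n_pairs, v0):
    """Per-trial EV of the chosen option and pre-update prediction error.

    Missed trials get NaN in both outputs.
    """
    n = pair.shape[0]
    ev = np.full(n, np.nan)
    delta = np.full(n, np.nan)
    v_cor = np.full(n_pairs, v0)
    v_inc = np.full(n_pairs, v0)
    for t in range(n):
        if missed[t]:
            continue
        p = pair[t]
        if chose_correct[t] == 1:
            ev[t] = v_cor[p]
            delta[t] = rewarded[t] - v_cor[p]
            v_cor[p] += alpha * delta[t]
        else:
            ev[t] = v_inc[p]
            delta[t] = rewarded[t] - v_inc[p]
            v_inc[p] += alpha * delta[t]
    return ev, delta


@njit(cache=False)
def _run_simulate(pair, reward_if_correct, reward_if_incorrect, missed,
                  alpha, beta, n_pairs, v0, u_choice):
    """Forward-simulate one run; returns (chose_correct, rewarded) with -1 at misses."""
    n = pair.shape[0]
    chose = np.full(n, -1)
    rewarded = np.full(n, -1)
    v_cor = np.full(n_pairs, v0)
    v_inc = np.full(n_pairs, v0)
    for t in range(n):
        if missed[t]:
            continue
        p = pair[t]
        z = beta * (v_cor[p] - v_inc[p])
        p_cor = 1.0 / (1.0 + np.exp(-z)) if z >= 0 else np.exp(z) / (1.0 + np.exp(z))
        if u_choice[t] < p_cor:
            chose[t] = 1
            rewarded[t] = reward_if_correct[t]
            v_cor[p] += alpha * (rewarded[t] - v_cor[p])
        else:
            chose[t] = 0
            rewarded[t] = reward_if_incorrect[t]
            v_inc[p] += alpha * (rewarded[t] - v_inc[p])
    return chose, rewarded


def _run_arrays(run: pd.DataFrame):
    pair = run["pair_id"].to_numpy(dtype=np.int64)
    missed = run["missed"].to_numpy(dtype=np.bool_)
    chose = run["chose_correct"].fillna(-1).to_numpy(dtype=np.int64)
    rewarded = run["rewarded"].fillna(-1).to_numpy(dtype=np.float64)
    return pair, chose, rewarded, missed


def _iter_runs(trials: pd.DataFrame):
    for run_index, run in trials.groupby("run_index", sort=True):
        run = run.sort_values("trial_index")
        cond = Condition(run["effort_level"].iloc[0], run["reward_level"].iloc[0])
        yield run_index, cond, run


def compile_trials(trials: pd.DataFrame) -> list[tuple]:
    """Pre-extract per-run arrays so repeated likelihood calls skip pandas.

    Returns one tuple per run: (condition, pair, chose_correct, rewarded,
    missed, n_pairs). Useful when an optimizer evaluates the likelihood
    many times on the same trials.
    """
    compiled = []
    for _, cond, run in _iter_runs(trials):
        pair, chose, rewarded, missed = _run_arrays(run)
        compiled.append((cond, pair, chose, rewarded, missed, int(pair.max()) + 1))
    return compiled


def negative_log_likelihood(
    params: AgentParams, trials, age_z: float = 0.0
) -> float:
    """Summed -log choice probability of the observed choices.

    One forward pass per run with that run's linked (alpha, beta); values
    reset at each run start (each run uses new stimuli). Missed trials
    contribute nothing and trigger no update. ``trials`` is a trial
    table or the output of :func:`compile_trials`.
    """
    if isinstance(trials, pd.DataFrame):
        trials = compile_trials(trials)
    nll = 0.0
    for cond, pair, chose, rewarded, missed, n_pairs in trials:
        alpha, beta = link_parameters(params, cond, age_z)
        nll += _run_nll(pair, chose, rewarded, missed, alpha, beta, n_pairs, V0)
    if not np.isfinite(nll):
        raise LikelihoodError("non-finite negative log-likelihood")
    return float(nll)


def compute_trajectories(
    params: AgentParams, trials: pd.DataFrame, age_z: float = 0.0
) -> pd.DataFrame:
    """Latent per-trial quantities of the fitted model.

    Returns one row per non-missed trial: run_index, trial_index,
    stim_onset_s, feedback_onset_s, alpha_t, beta_t, ev_chosen (value of
    the chosen option at stimulus onset), delta (pre-update prediction
    error at feedback onset) and pe_sign ('positive' for delta >= 0).
    """
    frames = []
    for run_index, cond, run in _iter_runs(trials):
        alpha, beta = link_parameters(params, cond, age_z)
        pair, chose, rewarded, missed = _run_arrays(run)
        n_pairs = int(pair.max()) + 1
        ev, delta = _run_traj(pair, chose, rewarded, missed, alpha, beta, n_pairs, V0)
        out = run[
            ["run_index", "trial_index", "stim_onset_s", "feedback_onset_s",
             "effort_level", "reward_level"]
        ].copy()
        out["alpha_t"] = alpha
        out["beta_t"] = beta
        out["ev_chosen"] = ev
        out["delta"] = delta
        frames.append(out[~missed])
    traj = pd.concat(frames, ignore_index=True)
    traj["pe_sign"] = np.where(traj["delta"] >= 0, "positive", "negative")
    return traj


def simulate_choices(
    params: AgentParams,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    age_z: float = 0.0,
) -> pd.DataFrame:
    """Generate choices and outcomes for scheduled trials.

    ``trials`` must carry run_index, trial_index, effort_level,
    reward_level, pair_id, reward_if_correct, reward_if_incorrect and a
    ``missed`` flag; returns a copy with chose_correct and rewarded
    filled in (NaN on missed trials).
    """
    out = []
    for _, cond, run in _iter_runs(trials):
        alpha, beta = link_parameters(params, cond, age_z)
        pair = run["pair_id"].to_numpy(dtype=np.int64)
        missed = run["missed"].to_numpy(dtype=np.bool_)
        ric = run["reward_if_correct"].to_numpy(dtype=np.int64)
        rii = run["reward_if_incorrect"].to_numpy(dtype=np.int64)
        n_pairs = int(pair.max()) + 1
        u = rng.random(len(run))
        chose, rewarded = _run_simulate(
            pair, ric, rii, missed, alpha, beta, n_pairs, V0, u
        )
        run = run.copy()
        run["chose_correct"] = np.where(chose < 0, np.nan, chose)
        run["rewarded"] = np.where(rewarded < 0, np.nan, rewarded)
        out.append(run)
    return pd.concat(out, ignore_index=True)


def trajectory_events_table(traj: pd.DataFrame, subject) -> pd.DataFrame:
    """Long serializable form: one row per EV / signed-PE event."""
    ev = traj[["run_index", "trial_index", "stim_onset_s", "ev_chosen"]].rename(
        columns={"stim_onset_s": "onset_s", "ev_chosen": "value"}
    )
    ev["event_type"] = "ev"
    pe = traj[["run_index", "trial_index", "feedback_onset_s", "delta", "pe_sign"]].rename(
        columns={"feedback_onset_s": "onset_s", "delta": "value"}
    )
    pe["event_type"] = np.where(pe["pe_sign"] == "positive", "pe_pos", "pe_neg")
    pe = pe.drop(columns="pe_sign")
    out = pd.concat([ev, pe], ignore_index=True)
    out.insert(0, "subject", subject)
    return out.sort_values(["run_index", "onset_s"]).reset_index(drop=True)
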