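"""Mixed-effects logistic analyses of trial-level accuracy.

Accuracy (correct = 1, incorrect = 0; missed trials dropped) is modeled
with fixed effects built from -1/+1 contrast codes (effort, reward, SV
group) and standardized continuous covariates (age, trial), plus a
random intercept per participant. Follow-up analyses refit reduced
models on subsets (per effort level, per effort x SV group, per age
bin) with their standardization recomputed inside the subset, and
Bonferroni-multiply the p-values by the number of subset models (2 for
per-effort, 4 for per-effort-and-SV-group).
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glmm import MixedLogitResult, fit_mixed_logit

__all__ = [
    "prepare_design",
    "expand_terms",
    "fit_logistic_mixed",
    "bonferroni_adjust",
    "follow_up_suite",
    "age_bin",
    "AGE_BINS",
    "MAIN_TERMS",
    "SV_TERMS",
]

#: Inclusive integer-age bins for the age-group follow-ups.
AGE_BINS = ((13, 15), (16, 18), (19, 21), (22, 25))

_BASE_COLUMNS = {
    "effort": "effort_code",
    "reward": "reward_code",
    "sv": "sv_code",
    "age": "age_z",
    "trial": "trial_z",
}


class StandardizationError(ValueError):
    """Raised when a covariate has zero variance within the analysis set."""


def expand_terms(factors: Sequence[str]) -> list[str]:
    """All main effects and interactions of the given factors."""
    terms = []
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(":".join(combo))
    return terms


MAIN_TERMS = expand_terms(["effort", "reward", "age", "trial"])
SV_TERMS = expand_terms(["effort", "reward", "age", "trial", "sv"])


def prepare_design(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    analysis_scope: pd.Series | None = None,
) -> pd.DataFrame:
    """Join trials to subject covariates and apply the coding rules.

    Missed trials are dropped; continuous covariates (age, within-run
    trial index) are standardized over the retained rows — so a subset
    analysis passes its subset here and gets subset standardization —
    and categorical levels become -1/+1 codes.
    """
    subj_cols = ["subject", "age"]
    if "sv_code" in subjects.columns:
        subj_cols += ["sv", "sv_group", "sv_code"]
    design = trials.merge(subjects[subj_cols], on="subject", how="left")
    if analysis_scope is not None:
        design = design[analysis_scope.reindex(design.index, fill_value=False)]
    design = design[~design["missed"].astype(bool)].copy()
    design["accuracy"] = design["chose_correct"].astype(int)
    design["effort_code"] = np.where(design["effort_level"] == "high", 1, -1)
    design["reward_code"] = np.where(design["reward_level"] == "high", 1, -1)
    for src, dst in (("age", "age_z"), ("trial_index", "trial_z")):
        x = design[src].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise StandardizationError(f"covariate {src!r} has zero variance")
        design[dst] = (x - x.mean()) / sd
    return design


def _design_matrix(design: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(design))]
    for term in terms:
        col = np.ones(len(design))
        for factor in term.split(":"):
            col = col * design[_BASE_COLUMNS[factor]].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def fit_logistic_mixed(
    design: pd.DataFrame,
    fixed_terms: Sequence[str] = MAIN_TERMS,
    bonferroni_m: int = 1,
    **glmm_kwargs,
) -> pd.DataFrame:
    """Fit the random-intercept logistic model and tabulate coefficients.

    Term names combine 'effort', 'reward', 'sv', 'age', 'trial' with ':'
    for interactions; an intercept is always included. Returns one row
    per fixed term with the log-odds estimate, Wald SE / z / p, the
    Bonferroni-adjusted p, and the random-intercept SD; convergence or
    separation problems are carried in a 'flags' column.
    """
    X = _design_matrix(design, fixed_terms)
    names = ["intercept"] + list(fixed_terms)
    result = fit_mixed_logit(
        X,
        design["accuracy"].to_numpy(dtype=float),
        design["subject"].to_numpy(),
        exog_names=names,
        **glmm_kwargs,
    )
    table = result.summary_frame().reset_index(names="term")
    table["p_bonferroni"] = bonferroni_adjust(table["p"].to_numpy(), bonferroni_m)
    table["ri_sd"] = result.sigma_u
    table["converged"] = result.converged
    table["flags"] = "; ".join(result.flags)
    return table


def bonferroni_adjust(p, m: int):
    """min(1, p * m) — the multiply-and-cap correction for m sub-analyses."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, p * m)
    return float(out) if out.ndim == 0 else out


def age_bin(age: float) -> str | None:
    """Inclusive integer-year bin label; fractional ages truncate."""
    year = int(age)
    for lo, hi in AGE_BINS:
        if lo <= year <= hi:
            return f"{lo}-{hi}"
    return None


def follow_up_suite(
    trials: pd.DataFrame,
    subjects: pd.DataFrame,
    scheme: str,
    **glmm_kwargs,
) -> dict[str, pd.DataFrame]:
    """Refit reduced models on the scheme's subsets.

    ``per_effort``: one model per effort level (reward, age, trial and
    the reward:age interaction), Bonferroni x2. ``per_effort_and_sv``:
    one reward-effect model per effort level x SV group, Bonferroni x4.
    ``per_age_group``: the effort/reward/trial model inside each of the
    four age bins, Bonferroni x4. Standardization is recomputed within
    every subset; empty subsets are skipped with a warning.
    """
    if scheme == "per_effort":
        subsets = [(f"effort={lev}", trials["effort_level"] == lev) for lev in ("low", "high")]
        terms = ["reward", "age", "trial", "reward:age"]
        m = 2
    elif scheme == "per_effort_and_sv":
        sv_of = subjects.set_index("subject")["sv_group"]
        subsets = []
        for lev in ("low", "high"):
            for grp in ("low", "high"):
                mask = (trials["effort_level"] == lev) & (
                    trials["subject"].map(sv_of) == grp
                )
                subsets.append((f"effort={lev},sv={grp}", mask))
        terms = ["reward", "age", "trial"]
        m = 4
    elif scheme == "per_age_group":
        bins = trials["subject"].map(subjects.set_index("subject")["age"]).map(age_bin)
        subsets = [(f"age={label}", bins == label) for label in
                   [f"{lo}-{hi}" for lo, hi in AGE_BINS]]
        terms = ["effort", "reward", "trial", "effort:reward"]
        m = 4
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    results: dict[str, pd.DataFrame] = {}
    for label, mask in subsets:
        sub = trials[mask.to_numpy()]
        if len(sub) == 0 or sub["subject"].nunique() < 2:
            warnings.warn(f"subset {label} empty or single-subject; skipped", stacklevel=2)
            continue
        design = prepare_design(sub, subjects)
        table = fit_logistic_mixed(design, terms, bonferroni_m=m, **glmm_kwargs)
        table["scope"] = label
        results[label] = table
    return results
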