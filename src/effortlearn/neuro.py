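"""Model-based fMRI predictors and ROI-level analyses.

From a fitted subject's latent trajectory this module builds the
six-predictor event structure of the run-level GLM — modulated and
unmodulated positive-PE, negative-PE and expected-value events, all with
zero duration, plus missed trials as zero-weight events — with the
modulated weights mean-centered per participant per regressor per
condition and never orthogonalized or standardized. Events convolve
with a canonical double-gamma HRF into per-volume design columns and
serialize as FSL 3-column EV files.

ROI analyses use 8 mm spheres on a 2 mm MNI grid around dACC [4 36 20],
vmPFC [0 34 0] and dorsal striatum [10 14 -6] / [-10 4 -6], and a
repeated-measures ANOVA on subject x condition betas with effort and
reward as within factors and standardized age as a continuous
covariate (Type III; each 1-df within contrast tested against its own
error stratum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .behavior import bonferroni_adjust

__all__ = [
    "EventSet",
    "ROISpec",
    "DEFAULT_ROIS",
    "build_event_sets",
    "double_gamma_hrf",
    "hrf_convolve",
    "temporal_derivative",
    "write_ev3",
    "read_ev3",
    "make_roi_mask",
    "roi_mask_to_nifti",
    "rm_anova",
    "roi_follow_up",
]

EVENT_NAMES = (
    "pe_pos_mod", "pe_pos_unmod", "pe_neg_mod", "pe_neg_unmod",
    "ev_mod", "ev_unmod", "missed",
)


class AlignmentError(ValueError):
    """Raised when trajectory rows and trial onsets do not line up."""


@dataclass
class EventSet:
    """One predictor's events for one run: onsets, durations, weights."""

    name: str
    run_index: int
    onsets: np.ndarray
    durations: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.onsets) == len(self.durations) == len(self.weights)):
            raise ValueError("onsets, durations, weights must have equal length")

    def __len__(self) -> int:
        return len(self.onsets)


def build_event_sets(trajectory: pd.DataFrame, trials: pd.DataFrame) -> list[EventSet]:
    """Assemble the seven event sets per run.

    ``trajectory`` is the non-missed per-trial table from the fitted
    model (delta at feedback onset, EV of the chosen option at stimulus
    onset); ``trials`` supplies the full schedule including missed
    trials. Zero prediction errors join the positive set. Modulated
    weights are mean-centered within each run (each run is one
    condition of one participant); unmodulated weights are 1 and missed
    events 0.
    """
    needed = {"run_index", "trial_index", "delta", "ev_chosen",
              "stim_onset_s", "feedback_onset_s"}
    if not needed.issubset(trajectory.columns):
        raise AlignmentError(f"trajectory missing columns {needed - set(trajectory.columns)}")
    merged = trajectory.merge(
        trials[["run_index", "trial_index"]], on=["run_index", "trial_index"], how="left",
        indicator=True,
    )
    if (merged["_merge"] != "both").any():
        raise AlignmentError("trajectory rows without matching trials")

    out: list[EventSet] = []
    for run_index, run_trials in trials.groupby("run_index", sort=True):
        traj = trajectory[trajectory["run_index"] == run_index]
        pos = traj[traj["delta"] >= 0]
        neg = traj[traj["delta"] < 0]
        zeros = lambda n: np.zeros(n)

        def centered(values: np.ndarray) -> np.ndarray:
            return values - values.mean() if len(values) else values

        out.append(EventSet("pe_pos_mod", run_index, pos["feedback_onset_s"].to_numpy(),
                            zeros(len(pos)), centered(pos["delta"].to_numpy())))
        out.append(EventSet("pe_pos_unmod", run_index, pos["feedback_onset_s"].to_numpy(),
                            zeros(len(pos)), np.ones(len(pos))))
        out.append(EventSet("pe_neg_mod", run_index, neg["feedback_onset_s"].to_numpy(),
                            zeros(len(neg)), centered(neg["delta"].to_numpy())))
        out.append(EventSet("pe_neg_unmod", run_index, neg["feedback_onset_s"].to_numpy(),
                            zeros(len(neg)), np.ones(len(neg))))
        out.append(EventSet("ev_mod", run_index, traj["stim_onset_s"].to_numpy(),
                            zeros(len(traj)), centered(traj["ev_chosen"].to_numpy())))
        out.append(EventSet("ev_unmod", run_index, traj["stim_onset_s"].to_numpy(),
                            zeros(len(traj)), np.ones(len(traj))))
        missed = run_trials[run_trials["missed"].astype(bool)]
        out.append(EventSet("missed", run_index, missed["stim_onset_s"].to_numpy(),
                            zeros(len(missed)), zeros(len(missed))))
    return out


def double_gamma_hrf(t: np.ndarray, peak_delay: float = 6.0,
                     undershoot_delay: float = 16.0, ratio: float = 1.0 / 6.0,
                     dispersion: float = 1.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    h = (
        stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
        - ratio * stats.gamma.pdf(t, undershoot_delay / dispersion, scale=dispersion)
    )
    peak = h.max()
    return h / peak if peak > 0 else h


def hrf_convolve(events: EventSet, tr: float = 2.0, n_volumes: int = 0,
                 dt: float = 0.05, hrf_length: float = 32.0) -> np.ndarray:
    """HRF-convolved design column sampled at volume acquisition times.

    Each event is an impulse of its weight at its onset on a dense
    ``dt`` grid; the convolution with the double-gamma response is then
    read out at t = 0, TR, 2 TR, ... The operation is linear in the
    weights and all-zero weights give an all-zero column.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    run_end = n_volumes * tr
    if len(events) and events.onsets.max() >= run_end:
        raise ValueError("event onset beyond the scanned run")
    n_dense = int(np.ceil((run_end + hrf_length) / dt)) + 1
    impulses = np.zeros(n_dense)
    for onset, weight in zip(events.onsets, events.weights):
        impulses[int(round(onset / dt))] += weight
    kernel = double_gamma_hrf(np.arange(0.0, hrf_length + dt, dt))
    dense = np.convolve(impulses, kernel)[:n_dense]
    volume_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return dense[volume_idx]


def temporal_derivative(regressor: np.ndarray) -> np.ndarray:
    """First-difference temporal derivative of a convolved column."""
    return np.diff(np.asarray(regressor, dtype=float), prepend=0.0)


def write_ev3(events: EventSet, path) -> None:
    """Write an FSL 3-column EV file (onset, duration, weight; 6 d.p.)."""
    lines = [
        f"{onset:.6f}\t{dur:.6f}\t{weight:.6f}"
        for onset, dur, weight in zip(events.onsets, events.durations, events.weights)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_ev3(path, name: str = "", run_index: int = 0) -> EventSet:
    """Read a 3-column EV file back into an EventSet."""
    onsets, durations, weights = [], [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        o, d, w = line.split("\t")
        onsets.append(float(o))
        durations.append(float(d))
        weights.append(float(w))
    return EventSet(name or Path(path).stem, run_index,
                    np.array(onsets), np.array(durations), np.array(weights))


@dataclass(frozen=True)
class ROISpec:
    """A spherical region of interest on the MNI 2 mm grid."""

    name: str
    center: tuple[float, float, float]
    radius: float = 8.0
    grid: float = 2.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.grid <= 0:
            raise ValueError("radius and grid must be positive")


DEFAULT_ROIS = {
    "dACC": ROISpec("dACC", (4.0, 36.0, 20.0)),
    "vmPFC": ROISpec("vmPFC", (0.0, 34.0, 0.0)),
    "striatum_R": ROISpec("striatum_R", (10.0, 14.0, -6.0)),
    "striatum_L": ROISpec("striatum_L", (-10.0, 4.0, -6.0)),
}


def make_roi_mask(spec: ROISpec) -> np.ndarray:
    """Voxel centers (mm) within the sphere, boundary inclusive.

    Voxel centers lie on multiples of the grid spacing, matching the
    MNI152 2 mm template grid for the default spacing.
    """
    c = np.asarray(spec.center, dtype=float)
    lo = np.floor((c - spec.radius) / spec.grid).astype(int)
    hi = np.ceil((c + spec.radius) / spec.grid).astype(int)
    axes = [np.arange(lo[d], hi[d] + 1) * spec.grid for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    dist = np.linalg.norm(pts - c, axis=1)
    return pts[dist <= spec.radius + 1e-9]


def roi_mask_to_nifti(spec: ROISpec, path) -> None:
    """Write the sphere as a binary NIfTI on the MNI152 2 mm grid."""
    import nibabel as nib

    affine = np.array(
        [[-2.0, 0.0, 0.0, 90.0],
         [0.0, 2.0, 0.0, -126.0],
         [0.0, 0.0, 2.0, -72.0],
         [0.0, 0.0, 0.0, 1.0]]
    )
    data = np.zeros((91, 109, 91), dtype=np.uint8)
    inv = np.linalg.inv(affine)
    for x, y, z in make_roi_mask(spec):
        i, j, k, _ = inv @ np.array([x, y, z, 1.0])
        i, j, k = int(round(i)), int(round(j)), int(round(k))
        if 0 <= i < 91 and 0 <= j < 109 and 0 <= k < 91:
            data[i, j, k] = 1
    nib.save(nib.Nifti1Image(data, affine), str(path))


def _contrast_scores(wide: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-subject within-condition contrast scores from the 2x2 cells."""
    cells = {
        (e, r): wide[f"{e}_{r}"].to_numpy(dtype=float)
        for e in ("low", "high") for r in ("low", "high")
    }
    return {
        "mean": sum(cells.values()) / 4.0,
        "effort": (cells[("high", "low")] + cells[("high", "high")]
                   - cells[("low", "low")] - cells[("low", "high")]) / 2.0,
        "reward": (cells[("low", "high")] + cells[("high", "high")]
                   - cells[("low", "low")] - cells[("high", "low")]) / 2.0,
        "effort:reward": (cells[("high", "high")] - cells[("high", "low")]
                          - cells[("low", "high")] + cells[("low", "low")]) / 2.0,
    }


def _score_regression_rows(score: np.ndarray, age_z: np.ndarray,
                           effect: str, test_intercept: bool) -> list[dict]:
    """F-tests from regressing one contrast score on [1, age_z]."""
    rows = []
    df2 = len(score) - 2
    label = "age" if effect == "mean" else f"{effect}:age"
    if np.allclose(score, 0.0):
        # a contrast that is identically zero carries no effect and no error
        if test_intercept:
            rows.append({"effect": effect, "F": 0.0, "df1": 1, "df2": df2, "p": 1.0})
        rows.append({"effect": label, "F": 0.0, "df1": 1, "df2": df2, "p": 1.0})
        return rows
    X = sm.add_constant(age_z)
    fit = sm.OLS(score, X).fit()
    if test_intercept:
        f = float(fit.tvalues[0] ** 2)
        rows.append({"effect": effect, "F": f, "df1": 1, "df2": df2,
                     "p": float(stats.f.sf(f, 1, df2))})
    f_age = float(fit.tvalues[1] ** 2)
    rows.append({"effect": label, "F": f_age, "df1": 1, "df2": df2,
                 "p": float(stats.f.sf(f_age, 1, df2))})
    return rows


def rm_anova(betas: pd.DataFrame, roi: str,
             within: Sequence[str] = ("effort", "reward")) -> pd.DataFrame:
    """Repeated-measures ANOVA on one ROI's betas with age as covariate.

    With both within factors, tests effort, reward, effort:reward, age,
    and every interaction with age; with ``within=('reward',)`` (the
    follow-up form) the reward difference ignores effort. Age is
    standardized over the subjects in the table, so the within-effect
    tests are evaluated at the mean age (Type III). Requires a complete
    2x2 (or 2-cell) design per subject.
    """
    sub = betas[betas["roi"] == roi]
    if sub.empty:
        raise ValueError(f"no rows for roi {roi!r}")
    if tuple(within) not in (("effort", "reward"), ("reward",), ("effort",)):
        raise ValueError(f"unsupported within factors {within!r}")

    if tuple(within) == ("effort", "reward"):
        wide = sub.pivot_table(index="subject", columns=["effort_level", "reward_level"],
                               values="beta")
        if wide.isna().any().any() or wide.shape[1] != 4:
            raise ValueError("incomplete 2x2 within design")
        wide.columns = [f"{e}_{r}" for e, r in wide.columns]
        scores = _contrast_scores(wide)
    else:
        factor = within[0]
        col = f"{factor}_level"
        wide = sub.pivot_table(index="subject", columns=col, values="beta")
        if wide.isna().any().any() or wide.shape[1] != 2:
            raise ValueError(f"incomplete within design for {factor}")
        scores = {
            "mean": (wide["high"].to_numpy() + wide["low"].to_numpy()) / 2.0,
            factor: wide["high"].to_numpy() - wide["low"].to_numpy(),
        }

    ages = sub.groupby("subject")["age"].first().reindex(wide.index).to_numpy(dtype=float)
    sd = ages.std()
    age_z = (ages - ages.mean()) / (sd if sd > 0 else 1.0)

    rows: list[dict] = []
    for effect, score in scores.items():
        rows.extend(_score_regression_rows(score, age_z, effect,
                                           test_intercept=(effect != "mean")))
    out = pd.DataFrame(rows)
    out.insert(0, "roi", roi)
    return out


def roi_follow_up(betas: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Reward-effect RM-ANOVAs on subsets, Bonferroni-adjusted.

    ``per_effort``: per effort level (2 models per ROI, p x2).
    ``per_sv_group``: per effort level x SV group (4 models per ROI,
    p x4); requires an ``sv_group`` column. Empty subsets are skipped
    with a warning.
    """
    if scheme == "per_effort":
        subsets = [({"effort_level": lev}, f"effort={lev}") for lev in ("low", "high")]
        m = 2
    elif scheme == "per_sv_group":
        if "sv_group" not in betas.columns:
            raise ValueError("per_sv_group scheme needs an sv_group column")
        subsets = [
            ({"effort_level": lev, "sv_group": grp}, f"effort={lev},sv={grp}")
            for lev in ("low", "high") for grp in ("low", "high")
        ]
        m = 4
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    frames = []
    for selector, label in subsets:
        mask = np.ones(len(betas), dtype=bool)
        for col, value in selector.items():
            mask &= (betas[col] == value).to_numpy()
        sub = betas[mask]
        if sub.empty:
            warnings.warn(f"subset {label} empty; skipped", stacklevel=2)
            continue
        for roi in sub["roi"].unique():
            table = rm_anova(sub, roi, within=("reward",))
            table["scope"] = label
            frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    out["p_bonferroni"] = bonferroni_adjust(out["p"].to_numpy(), m)
    return out
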