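"""fMRI predictors and ROI analyses: centering, HRF, masks, RM-ANOVA oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from effortlearn import cohort, neuro, rw

from conftest import toy_trials


@pytest.fixture(scope="module")
def subject_events(tiny_cohort):
    trials = tiny_cohort.trials[tiny_cohort.trials["subject"] == 0]
    params = rw.AgentParams(alpha_base=-0.8, beta_base=1.2, a_reward=0.2)
    traj = rw.compute_trajectories(params, trials)
    return trials, traj, neuro.build_event_sets(traj, trials)


def test_modulated_weights_centered_per_cell(subject_events):
    _, _, events = subject_events
    for ev in events:
        if ev.name.endswith("_mod") and len(ev):
            assert abs(ev.weights.mean()) < 1e-12
        if ev.name.endswith("_unmod"):
            assert (ev.weights == 1.0).all()
        if ev.name == "missed":
            assert (ev.weights == 0.0).all()
        assert (ev.durations == 0.0).all()


def test_event_counts_partition_trials(subject_events):
    trials, _, events = subject_events
    by_run = {(e.run_index, e.name): len(e) for e in events}
    for run_index, run in trials.groupby("run_index"):
        total = (
            by_run[(run_index, "pe_pos_mod")]
            + by_run[(run_index, "pe_neg_mod")]
            + by_run[(run_index, "missed")]
        )
        assert total == len(run)
        assert by_run[(run_index, "ev_mod")] == (~run["missed"]).sum()


def test_centering_worked_example():
    trials = toy_trials([
        (0, "low", "low", 0, 1, 1, False),
        (0, "low", "low", 0, 1, 1, False),
        (0, "low", "low", 0, 1, 1, False),
    ])
    traj = pd.DataFrame({
        "run_index": [0, 0, 0],
        "trial_index": [0, 1, 2],
        "delta": [0.2, 0.4, 0.6],
        "ev_chosen": [0.5, 0.56, 0.63],
        "stim_onset_s": [2.0, 12.0, 22.0],
        "feedback_onset_s": [7.0, 17.0, 27.0],
    })
    events = {e.name: e for e in neuro.build_event_sets(traj, trials)}
    assert np.allclose(events["pe_pos_mod"].weights, [-0.2, 0.0, 0.2])


def test_run_without_negative_pes_yields_empty_sets():
    trials = toy_trials([(0, "low", "low", 0, 1, 1, False)] * 2)
    traj = pd.DataFrame({
        "run_index": [0, 0], "trial_index": [0, 1],
        "delta": [0.5, 0.35], "ev_chosen": [0.5, 0.65],
        "stim_onset_s": [2.0, 12.0], "feedback_onset_s": [7.0, 17.0],
    })
    events = {e.name: e for e in neuro.build_event_sets(traj, trials)}
    assert len(events["pe_neg_mod"]) == 0
    assert len(events["pe_neg_unmod"]) == 0
    # zero deltas would join the positive set by the documented tie-break
    traj.loc[1, "delta"] = 0.0
    events = {e.name: e for e in neuro.build_event_sets(traj, trials)}
    assert len(events["pe_pos_mod"]) == 2


def test_misaligned_trajectory_raises():
    trials = toy_trials([(0, "low", "low", 0, 1, 1, False)])
    traj = pd.DataFrame({
        "run_index": [0], "trial_index": [5], "delta": [0.5],
        "ev_chosen": [0.5], "stim_onset_s": [2.0], "feedback_onset_s": [7.0],
    })
    with pytest.raises(neuro.AlignmentError):
        neuro.build_event_sets(traj, trials)


def _dense_oracle_regressor(events, tr, n_volumes):
    """Independent numerical convolution on a fine grid."""
    dt = 0.005
    t = np.arange(0.0, n_volumes * tr + 40.0, dt)
    signal = np.zeros_like(t)
    hrf = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    hrf = hrf / hrf.max()
    for onset, weight in zip(events.onsets, events.weights):
        shifted = t - onset
        signal += weight * np.interp(shifted, t, hrf, left=0.0)
    idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return signal[idx]


def test_hrf_unit_impulse_peaks_near_six_seconds():
    ev = neuro.EventSet("pe_pos_unmod", 0, [0.0], [0.0], [1.0])
    reg = neuro.hrf_convolve(ev, tr=2.0, n_volumes=16)
    assert np.argmax(reg) == 3  # sampled time 6 s
    oracle = _dense_oracle_regressor(ev, 2.0, 16)
    assert np.allclose(reg, oracle, atol=5e-3)


def test_hrf_linearity_and_zero_weights():
    rng = np.random.default_rng(0)
    onsets_a = np.sort(rng.uniform(0, 100, 8))
    onsets_b = np.sort(rng.uniform(0, 100, 5))
    wa, wb = rng.normal(size=8), rng.normal(size=5)
    a = neuro.EventSet("a", 0, onsets_a, np.zeros(8), wa)
    b = neuro.EventSet("b", 0, onsets_b, np.zeros(5), wb)
    union = neuro.EventSet("ab", 0, np.concatenate([onsets_a, onsets_b]),
                           np.zeros(13), np.concatenate([wa, wb]))
    n_vol = 70
    assert np.allclose(
        neuro.hrf_convolve(union, 2.0, n_vol),
        neuro.hrf_convolve(a, 2.0, n_vol) + neuro.hrf_convolve(b, 2.0, n_vol),
        atol=1e-12,
    )
    silent = neuro.EventSet("z", 0, onsets_a, np.zeros(8), np.zeros(8))
    assert (neuro.hrf_convolve(silent, 2.0, n_vol) == 0).all()


def test_hrf_shift_by_whole_volumes_shifts_samples():
    ev = neuro.EventSet("e", 0, [10.0], [0.0], [1.0])
    shifted = neuro.EventSet("e", 0, [14.0], [0.0], [1.0])  # +2 TR
    n_vol = 40
    a = neuro.hrf_convolve(ev, 2.0, n_vol)
    b = neuro.hrf_convolve(shifted, 2.0, n_vol)
    assert np.allclose(b[2:], a[:-2], atol=1e-12)


def test_temporal_derivative_is_first_difference():
    reg = np.array([0.0, 1.0, 3.0, 2.0])
    assert np.allclose(neuro.temporal_derivative(reg), [0.0, 1.0, 2.0, -1.0])


def test_ev3_round_trip(tmp_path, subject_events):
    _, _, events = subject_events
    ev = next(e for e in events if e.name == "pe_pos_mod" and len(e))
    path = tmp_path / "ev.txt"
    neuro.write_ev3(ev, path)
    back = neuro.read_ev3(path)
    assert np.allclose(back.onsets, np.round(ev.onsets, 6))
    assert (back.durations == 0.0).all()
    assert np.allclose(back.weights, np.round(ev.weights, 6))
    # empty set round trip
    empty = neuro.EventSet("pe_neg_mod", 0, [], [], [])
    neuro.write_ev3(empty, tmp_path / "empty.txt")
    assert len(neuro.read_ev3(tmp_path / "empty.txt")) == 0


def brute_force_sphere_count(center, radius, grid):
    count = 0
    r_vox = int(np.ceil(radius / grid)) + 2
    cx, cy, cz = (int(round(c / grid)) for c in center)
    for i in range(cx - r_vox, cx + r_vox + 1):
        for j in range(cy - r_vox, cy + r_vox + 1):
            for k in range(cz - r_vox, cz + r_vox + 1):
                d = np.sqrt(((i * grid - center[0]) ** 2)
                            + ((j * grid - center[1]) ** 2)
                            + ((k * grid - center[2]) ** 2))
                if d <= radius + 1e-9:
                    count += 1
    return count


@pytest.mark.parametrize("roi", list(neuro.DEFAULT_ROIS))
def test_roi_masks_match_brute_force_enumeration(roi):
    spec = neuro.DEFAULT_ROIS[roi]
    mask = neuro.make_roi_mask(spec)
    assert len(mask) == brute_force_sphere_count(spec.center, spec.radius, spec.grid)
    center = np.asarray(spec.center)
    assert any(np.allclose(v, center) for v in mask)
    # reflection symmetry through the center along each axis
    for axis in range(3):
        reflected = mask.copy()
        reflected[:, axis] = 2 * center[axis] - reflected[:, axis]
        assert {tuple(v) for v in np.round(reflected, 6)} == {
            tuple(v) for v in np.round(mask, 6)
        }


def test_roi_mask_nifti_written(tmp_path):
    import nibabel as nib

    spec = neuro.DEFAULT_ROIS["dACC"]
    path = tmp_path / "dacc.nii.gz"
    neuro.roi_mask_to_nifti(spec, path)
    img = nib.load(str(path))
    assert img.shape == (91, 109, 91)
    assert img.get_fdata().sum() == len(neuro.make_roi_mask(spec))


def rm_anova_oracle(betas, roi):
    """Closed-form within-contrast F tests, coded independently."""
    sub = betas[betas["roi"] == roi]
    wide = sub.pivot_table(index="subject", columns=["effort_level", "reward_level"],
                           values="beta")
    ll = wide[("low", "low")].to_numpy()
    lh = wide[("low", "high")].to_numpy()
    hl = wide[("high", "low")].to_numpy()
    hh = wide[("high", "high")].to_numpy()
    ages = sub.groupby("subject")["age"].first().reindex(wide.index).to_numpy()
    a = (ages - ages.mean()) / ages.std()
    n = len(a)

    scores = {
        "effort": (hl + hh - ll - lh) / 2.0,
        "reward": (lh + hh - ll - hl) / 2.0,
        "effort:reward": (hh - hl - lh + ll) / 2.0,
        "mean": (ll + lh + hl + hh) / 4.0,
    }
    out = {}
    for name, s in scores.items():
        saa = np.sum(a * a)
        b1 = np.sum(a * (s - s.mean())) / saa
        b0 = s.mean()  # a is centered
        resid = s - b0 - b1 * a
        mse = np.sum(resid**2) / (n - 2)
        f_int = b0**2 / (mse / n)
        f_slope = b1**2 / (mse / saa)
        if name == "mean":
            out["age"] = f_slope
        else:
            out[name] = f_int
            out[f"{name}:age"] = f_slope
    return out


def test_rm_anova_matches_contrast_oracle(tiny_cohort):
    table = neuro.rm_anova(tiny_cohort.roi_betas, "dACC")
    oracle = rm_anova_oracle(tiny_cohort.roi_betas, "dACC")
    got = table.set_index("effect")["F"]
    for effect, f in oracle.items():
        assert got[effect] == pytest.approx(f, abs=1e-8), effect
    assert (table["df1"] == 1).all()
    assert (table["df2"] == tiny_cohort.spec.n_subjects - 2).all()


def test_rm_anova_flat_betas_give_zero_within_F():
    subjects = pd.DataFrame({"subject": range(6),
                             "age": np.linspace(14, 24, 6),
                             "age_z": np.linspace(-1.2, 1.2, 6)})
    spec = cohort.PopulationSpec(
        n_subjects=6, roi_noise_sd=0.0,
        roi_effects={"dACC": {"intercept": 1.3}},
    )
    betas = cohort.simulate_roi_betas(spec, subjects, np.random.default_rng(0))
    # add subject-varying offsets so the error stratum is non-degenerate
    rng = np.random.default_rng(1)
    offsets = dict(zip(range(6), rng.normal(0, 0.5, 6)))
    betas["beta"] = betas["beta"] + betas["subject"].map(offsets)
    table = neuro.rm_anova(betas, "dACC").set_index("effect")
    for effect in ("effort", "reward", "effort:reward"):
        assert table.loc[effect, "F"] == pytest.approx(0.0, abs=1e-16)


def test_rm_anova_incomplete_design_rejected(tiny_cohort):
    betas = tiny_cohort.roi_betas
    broken = betas[~((betas["subject"] == 0) & (betas["effort_level"] == "low"))]
    with pytest.raises(ValueError):
        neuro.rm_anova(broken, "dACC")


def test_injected_interaction_detected_in_simulation():
    """The injected reward x effort effect outranks the null effects."""
    hits = 0
    n_reps = 20
    for rep in range(n_reps):
        subjects = pd.DataFrame({
            "subject": range(40),
            "age": np.linspace(13, 25, 40),
            "age_z": stats.zscore(np.linspace(13, 25, 40)),
        })
        spec = cohort.PopulationSpec(
            n_subjects=40, roi_noise_sd=0.5,
            roi_effects={"dACC": {"intercept": 1.0, "reward_effort": 0.3}},
        )
        betas = cohort.simulate_roi_betas(spec, subjects,
                                          np.random.default_rng(rep))
        table = neuro.rm_anova(betas, "dACC").set_index("effect")
        null_p = min(table.loc["effort", "p"], table.loc["reward", "p"])
        if table.loc["effort:reward", "p"] < null_p:
            hits += 1
    assert hits >= 18  # >= 90% of replicates


def test_roi_follow_up_schemes(tiny_cohort):
    per_effort = neuro.roi_follow_up(tiny_cohort.roi_betas, "per_effort")
    assert set(per_effort["scope"]) == {"effort=low", "effort=high"}
    assert np.allclose(per_effort["p_bonferroni"],
                       np.minimum(1.0, per_effort["p"] * 2))
    per_sv = neuro.roi_follow_up(tiny_cohort.roi_betas, "per_sv_group")
    assert np.allclose(per_sv["p_bonferroni"],
                       np.minimum(1.0, per_sv["p"] * 4))
    assert len(set(per_sv["scope"])) <= 4
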