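"""Mixed-effects accuracy analyses: coding rules, GLMM engine, Bonferroni."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from effortlearn import behavior
from effortlearn.glmm import fit_mixed_logit, likelihood_ratio_test


def _simulate_binary_panel(n_subjects, n_trials, beta_reward, sigma_u, seed,
                           intercept=0.0):
    """Trials with a known reward effect and random-intercept SD."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = sigma_u * rng.standard_normal()
        for t in range(n_trials):
            reward = 1 if t % 2 == 0 else -1
            eta = intercept + beta_reward * reward + u
            y = int(rng.random() < 1.0 / (1.0 + np.exp(-eta)))
            rows.append({"subject": s, "reward_code": reward, "accuracy": y})
    return pd.DataFrame(rows)


def test_prepare_design_standardizes_and_codes(tiny_cohort):
    design = behavior.prepare_design(tiny_cohort.trials, tiny_cohort.subjects)
    assert not design["missed"].any()
    for col in ("age_z", "trial_z"):
        assert abs(design[col].mean()) < 1e-12
        assert design[col].to_numpy().std() == pytest.approx(1.0, abs=1e-12)
    assert set(design["effort_code"]) == {-1, 1}
    assert set(design["reward_code"]) == {-1, 1}
    assert set(design["accuracy"]) <= {0, 1}
    # balanced runs: codes sum to ~0 over complete schedules (misses aside)
    full = tiny_cohort.trials
    assert (
        np.where(full["reward_level"] == "high", 1, -1).sum() == 0
    )


def test_subset_design_restandardizes_within_subset(tiny_cohort):
    high = tiny_cohort.trials[tiny_cohort.trials["effort_level"] == "high"]
    design = behavior.prepare_design(high, tiny_cohort.subjects)
    assert abs(design["trial_z"].mean()) < 1e-12
    assert design["trial_z"].to_numpy().std() == pytest.approx(1.0, abs=1e-12)
    assert design["trial_z"].abs().max() < 2.1  # 64-trial range, not 192


def test_zero_variance_covariate_raises(tiny_cohort):
    trials = tiny_cohort.trials.copy()
    subjects = tiny_cohort.subjects.copy()
    subjects["age"] = 17.0
    with pytest.raises(behavior.StandardizationError):
        behavior.prepare_design(trials, subjects)


def test_expand_terms_counts():
    assert len(behavior.MAIN_TERMS) == 15   # 4 factors, all interactions
    assert len(behavior.SV_TERMS) == 31     # 5 factors
    assert "effort:reward:age:trial" in behavior.MAIN_TERMS


def test_glmm_matches_pooled_logit_when_no_heterogeneity():
    """With zero true random-intercept variance the GLMM's fixed effects
    must agree with an ordinary pooled logistic fit within 2 SE."""
    data = _simulate_binary_panel(40, 60, beta_reward=0.4, sigma_u=0.0, seed=1)
    X = np.column_stack([np.ones(len(data)), data["reward_code"]])
    y = data["accuracy"].to_numpy(float)
    mixed = fit_mixed_logit(X, y, data["subject"].to_numpy(),
                            exog_names=["intercept", "reward"])
    pooled = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    for i, name in enumerate(["intercept", "reward"]):
        assert abs(mixed.params[name] - pooled.params[i]) <= 2 * pooled.bse[i]
    assert mixed.sigma_u < 0.2


def test_glmm_recovers_known_effect_and_intercept_sd():
    data = _simulate_binary_panel(60, 80, beta_reward=0.5, sigma_u=0.8, seed=2)
    X = np.column_stack([np.ones(len(data)), data["reward_code"]])
    mixed = fit_mixed_logit(X, data["accuracy"].to_numpy(float),
                            data["subject"].to_numpy(),
                            exog_names=["intercept", "reward"])
    assert abs(mixed.params["reward"] - 0.5) <= 2 * mixed.bse["reward"]
    assert 0.5 <= mixed.sigma_u <= 1.2
    assert mixed.converged


def test_glmm_agrees_with_lme4_reference(tmp_path):
    """Cross-check the adaptive-quadrature fit against glmer (nAGQ=15)."""
    data = _simulate_binary_panel(30, 40, beta_reward=0.3, sigma_u=0.6, seed=3,
                                  intercept=0.4)
    csv = tmp_path / "panel.csv"
    data.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(accuracy ~ reward_code + (1 | subject), data = d,
                   family = binomial, nAGQ = 15)
        co <- fixef(m)
        cat(sprintf("%.8f %.8f %.8f\\n", co[1], co[2],
                    sqrt(unlist(VarCorr(m))[1])))
    """)
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    r_int, r_reward, r_sigma = map(float, proc.stdout.split())

    X = np.column_stack([np.ones(len(data)), data["reward_code"]])
    mixed = fit_mixed_logit(X, data["accuracy"].to_numpy(float),
                            data["subject"].to_numpy(),
                            exog_names=["intercept", "reward"])
    assert mixed.params["intercept"] == pytest.approx(r_int, abs=2e-3)
    assert mixed.params["reward"] == pytest.approx(r_reward, abs=2e-3)
    assert mixed.sigma_u == pytest.approx(r_sigma, abs=2e-2)


def test_fit_logistic_mixed_table_layout(tiny_cohort):
    design = behavior.prepare_design(tiny_cohort.trials, tiny_cohort.subjects)
    table = behavior.fit_logistic_mixed(design, ["effort", "reward", "age"],
                                        bonferroni_m=2)
    assert table["term"].tolist() == ["intercept", "effort", "reward", "age"]
    assert (table["p_bonferroni"] >= table["p"]).all()
    assert (table["p_bonferroni"] <= 1.0).all()
    assert table["ri_sd"].nunique() == 1


@pytest.mark.parametrize(
    "p,m,expected",
    [(0.03, 4, 0.12), (0.04, 4, 0.16), (0.6, 2, 1.0), (0.2, 1, 0.2)],
)
def test_bonferroni_printed_arithmetic(p, m, expected):
    assert behavior.bonferroni_adjust(p, m) == pytest.approx(expected)


def test_bonferroni_rejects_bad_inputs():
    with pytest.raises(ValueError):
        behavior.bonferroni_adjust(1.2, 2)
    with pytest.raises(ValueError):
        behavior.bonferroni_adjust(0.5, 0)


def test_age_bins_partition_integer_and_fractional_ages():
    assert behavior.age_bin(13) == "13-15"
    assert behavior.age_bin(15.7) == "13-15"   # truncation rule
    assert behavior.age_bin(16.0) == "16-18"
    assert behavior.age_bin(25.0) == "22-25"
    ages = np.linspace(13.0, 25.0, 200)
    bins = [behavior.age_bin(a) for a in ages]
    assert all(b is not None for b in bins)


def test_follow_up_suite_schemes(tiny_cohort):
    per_effort = behavior.follow_up_suite(
        tiny_cohort.trials, tiny_cohort.subjects, "per_effort"
    )
    assert len(per_effort) == 2
    for table in per_effort.values():
        uncorrected = table["p"].to_numpy()
        assert np.allclose(
            table["p_bonferroni"], np.minimum(1.0, uncorrected * 2)
        )
    with pytest.raises(ValueError):
        behavior.follow_up_suite(tiny_cohort.trials, tiny_cohort.subjects, "bogus")


def test_likelihood_ratio_test_nested_order():
    data = _simulate_binary_panel(25, 40, beta_reward=0.5, sigma_u=0.5, seed=4)
    X_full = np.column_stack([np.ones(len(data)), data["reward_code"]])
    X_red = X_full[:, :1]
    y = data["accuracy"].to_numpy(float)
    groups = data["subject"].to_numpy()
    full = fit_mixed_logit(X_full, y, groups)
    reduced = fit_mixed_logit(X_red, y, groups)
    lr, df, p = likelihood_ratio_test(full, reduced)
    assert df == 1
    assert lr >= 0
    assert 0 <= p <= 1
    with pytest.raises(ValueError):
        likelihood_ratio_test(reduced, full)
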