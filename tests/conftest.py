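import numpy as np
import pandas as pd
import pytest

from effortlearn import cohort, task


@pytest.fixture(scope="session")
def config():
    return task.TaskConfig()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-subject cohort shared by the integration-style tests."""
    spec = cohort.PopulationSpec(n_subjects=6)
    return cohort.generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def single_subject_trials(tiny_cohort):
    return tiny_cohort.trials[tiny_cohort.trials["subject"] == 0].copy()


def toy_trials(rows):
    """Build a minimal trial table from (run, effort, reward, pair, chose, rewarded, missed)."""
    records = []
    for i, (run, effort, reward, pair, chose, rewarded, missed) in enumerate(rows):
        records.append(
            {
                "subject": 0,
                "run_index": run,
                "trial_index": i,
                "effort_level": effort,
                "reward_level": reward,
                "pair_id": pair,
                "chose_correct": np.nan if missed else chose,
                "rewarded": np.nan if missed else rewarded,
                "missed": missed,
                "stim_onset_s": 10.0 * i + 2.0,
                "feedback_onset_s": 10.0 * i + 7.0,
            }
        )
    return pd.DataFrame(records)
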