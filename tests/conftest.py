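"""Shared fixtures.

The reduced end-to-end study (60 subjects, 100 trials/task, 60 channels) is
expensive (~minutes), so it runs once per session and its report is shared by
every test that checks planted-truth recovery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from metacontrol.montage import default_montage
from metacontrol.pipeline import reduced_cohort_config, run_full
from metacontrol import synthetic_data as synth

# fixed once for the whole suite; all stage seeds derive from it
REDUCED_STUDY_SEED = 1


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small behavioral cohort for unit tests (fast)."""
    params = synth.CohortParams(n_subjects=16, n_trials_per_task=40, seed=11)
    return params, synth.generate_behavior(params)


@pytest.fixture(scope="session")
def reduced_study(tmp_path_factory):
    """The reduced validation study, run end to end once per session."""
    cfg = reduced_cohort_config(REDUCED_STUDY_SEED)
    out = tmp_path_factory.mktemp("reduced_study")
    report = run_full(cfg, out)
    return cfg, report, out


def make_epochs(data, sfreq=256.0, t0_ms=-2000.0, locking="stimulus",
                montage=None, units="potential", task="easy", correct=None):
    """Build an EpochSet around a raw array with minimal metadata."""
    from metacontrol.epochs import EpochSet

    data = np.asarray(data, float)
    if montage is None:
        montage = default_montage()
    n = data.shape[0]
    info = pd.DataFrame({
        "subject": np.ones(n, int),
        "task": [task] * n,
        "trial": np.arange(1, n + 1),
        "correct": np.ones(n, bool) if correct is None else correct,
        "rt_ms": np.full(n, 500.0),
    })
    return EpochSet(data=data, sfreq=sfreq, t0_ms=t0_ms, locking=locking,
                    montage=montage, trial_info=info, units=units)
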