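"""Shared fixtures.

The session-scoped multi-seed runs are the expensive part of the suite:
each run simulates 13 subjects x 3 conditions at 12 s / 500 Hz
(N = 6,000 per channel), preprocesses, extracts whole-head SampEn
features and evaluates both classifiers under LOOCV.  They are computed
once and shared between the property tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import eegattn as ea
from eegattn.classify import loocv
from eegattn.entropy import EntropyParams, extract_features
from eegattn.preprocess import preprocess_trial

TEST_DURATION = 12.0  # seconds -> N = 6,000 samples per channel
EFFECT_SEEDS = tuple(range(20))
NULL_SEEDS = tuple(range(100, 110))
FLAT_COMPLEXITY = {"Rest": 0.5, "AOA1": 0.5, "AOA2": 0.5}


def _one_run(seed: int, complexity=None, classifiers=("svm", "lda")):
    kwargs = {} if complexity is None else {"complexity_by_condition": dict(complexity)}
    config = ea.SimulationConfig(duration=TEST_DURATION, seed=seed, **kwargs)
    trials = [preprocess_trial(t) for t in ea.generate_dataset(config)]
    table = extract_features(trials, "sampen", EntropyParams())
    run = {"seed": seed, "table": table, "trials": trials}
    for kind in classifiers:
        run[kind] = loocv(table, kind, feature_spec="sampen")
    return run


@pytest.fixture(scope="session")
def effect_runs():
    """20 seeded datasets with the default condition-dependent complexity."""
    return [_one_run(seed) for seed in EFFECT_SEEDS]


@pytest.fixture(scope="session")
def null_runs():
    """10 seeded datasets with complexity differences removed."""
    return [_one_run(seed, complexity=FLAT_COMPLEXITY, classifiers=("svm",)) for seed in NULL_SEEDS]


@pytest.fixture(scope="session")
def cmpmse_table(effect_runs):
    """CmpMSE features (tau = 5, within the spectral-slope model's
    ordering validity domain) for the first default dataset."""
    return extract_features(effect_runs[0]["trials"], "cmpmse", EntropyParams(tau=5))


@pytest.fixture(scope="session")
def tiny_trials():
    """Two preprocessed subjects (6 trials) for structural checks."""
    config = ea.SimulationConfig(n_subjects=2, duration=TEST_DURATION, seed=7)
    return [preprocess_trial(t) for t in ea.generate_dataset(config)]


def group_means(table):
    labels = np.asarray(table.labels)
    return {c: table.values[labels == c].mean(axis=0) for c in ea.CONDITIONS}
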