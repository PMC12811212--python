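import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cqtc import ecg as ecg_mod
from cqtc.assemble import assemble_dataset
from cqtc.predict import PredictionScenario
from cqtc.simulate import (PkTruth, QtcTruth, TrialDesign, recovery_study,
                           simulate_trial)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def trial():
    """One simulated default trial (Parts 1-3, 40 subjects)."""
    return simulate_trial(TrialDesign.default(), PkTruth(), QtcTruth(), seed=123)


@pytest.fixture(scope="session")
def preprocessed(trial):
    points = ecg_mod.qtcf_points(trial.ecg)
    baselines = ecg_mod.compute_baselines(points)
    dq = ecg_mod.compute_dqtcf(points, baselines)
    return points, baselines, dq


@pytest.fixture(scope="session")
def matched(trial, preprocessed):
    _, baselines, dq = preprocessed
    m, excl = assemble_dataset(dq, trial.pk, trial.randomization, baselines)
    return m, excl


def random_small_dataset(rng, n_subjects=None, p=3):
    """A tiny mixed-model dataset (<=5 subjects, <=30 rows) with random
    truth, for likelihood-oracle comparisons."""
    n_subjects = n_subjects or int(rng.integers(3, 6))
    rows = []
    for s in range(n_subjects):
        ni = int(rng.integers(3, 7))
        rows.append(ni)
    n = sum(rows)
    X = np.column_stack([np.ones(n)] + [rng.normal(0, 1, n) for _ in range(p - 1)])
    x = rng.uniform(0, 2, n)
    Z = np.column_stack([np.ones(n), x])
    groups = np.repeat(np.arange(n_subjects), rows)
    A = rng.normal(0, 0.7, (2, 2))
    G = A @ A.T + 0.05 * np.eye(2)
    sigma = rng.uniform(0.5, 1.5)
    beta = rng.normal(0, 2, p)
    eta = rng.multivariate_normal(np.zeros(2), G, size=n_subjects)
    y = X @ beta + np.einsum("ij,ij->i", Z, eta[groups]) + rng.normal(0, sigma, n)
    return X, Z, y, groups


@pytest.fixture(scope="session")
def mc_study():
    """Shared Monte-Carlo study at the default design: 1000 full
    simulate->assemble->fit->predict replicates under the model-exact truth,
    with the Day-1 therapeutic-concentration scenario."""
    truth = QtcTruth.model_exact()
    scenario = PredictionScenario("therapeutic", 0.375, 0.0, day=1)
    results = recovery_study(1000, design=TrialDesign.default(),
                             pk_truth=PkTruth(), qtc_truth=truth, seed=0,
                             scenario=scenario)
    return results, truth
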