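"""Shared fixtures: small seeded datasets and reduced-cost fit settings."""

import numpy as np
import pytest

import heurfit as hf
from heurfit.simulate import SimulatedDecider


@pytest.fixture(scope="session")
def small_task():
    """A K=2 task small enough for dense-grid and Monte-Carlo oracles."""
    return hf.TaskConfig(k=2, n_trials=20)


@pytest.fixture(scope="session")
def fast_fit_config():
    """Reduced restarts/draws for unit tests (full accuracy not needed)."""
    return hf.FitConfig(n_restarts=4, n_importance=2000, seed=11)


def make_dataset(spec_id, w, beta, k=None, n_trials=100, seed=0, pid="p"):
    """Simulate one decider's dataset from known parameters."""
    spec = hf.ChoiceModelSpec.from_id(spec_id)
    w = np.asarray(w, dtype=float)
    task = hf.TaskConfig(k=len(w), n_trials=n_trials)
    trials = hf.generate_trials(task, seed=seed)
    dec = SimulatedDecider(spec=spec, w=w, beta=beta)
    return hf.simulate_choices(dec, trials, seed=seed + 1, participant_id=pid)


@pytest.fixture(scope="session")
def spec5_dataset():
    """100 trials from a take-the-best decider (+1 on attribute 3, beta=5)."""
    w = np.zeros(9)
    w[2] = 1.0
    return make_dataset(5, w, beta=5.0, seed=21)
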