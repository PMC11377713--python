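"""Shared fixtures: the default synthetic study and its factorizations.

Heavy objects are session-scoped so the acceptance-style checks and the
module tests share one simulation instead of regenerating it per test.
"""

import numpy as np
import pytest
from hypothesis import settings

from triomics.factor_eval import select_best
from triomics.jdr import run_all
from triomics.simulate import SimConfig, simulate_knowledge, simulate_multiomics

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim42():
    """Default synthetic study (18/13 samples, seed 42) plus ground truth."""
    mset, truth = simulate_multiomics(SimConfig(seed=42))
    return mset, truth


@pytest.fixture(scope="session")
def knowledge42(sim42):
    _, truth = sim42
    return simulate_knowledge(truth, SimConfig(seed=42))


@pytest.fixture(scope="session")
def labels42(sim42):
    mset, _ = sim42
    return [mset.labels.groups[s] for s in mset.sample_ids]


@pytest.fixture(scope="session")
def fzs42(sim42):
    """All three factorizations of the default synthetic set (k = 2)."""
    mset, _ = sim42
    return run_all(mset, k=2)


@pytest.fixture(scope="session")
def chosen42(fzs42, labels42):
    """Per-method best factors, scored with the full 1000 k-means runs."""
    scores, chosen = select_best(fzs42, labels42, n_runs=1000, seed=0)
    return scores, chosen


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
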