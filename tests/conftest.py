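"""Shared fixtures: small graphs and a reusable planted-effect cohort."""

import numpy as np
import pandas as pd
import pytest

import graphpm as g
from graphpm.cohort import SYMPTOMS, TIMEPOINTS
from graphpm.connectome import WeightedGraph


def path_graph(n: int, weight: float = 1.0) -> WeightedGraph:
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = weight
    return WeightedGraph(w)


def complete_graph(n: int, weight: float = 1.0) -> WeightedGraph:
    w = np.full((n, n), weight, dtype=float)
    np.fill_diagonal(w, 0.0)
    return WeightedGraph(w)


def cycle_graph(n: int, weight: float = 1.0) -> WeightedGraph:
    w = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        w[i, j] = w[j, i] = weight
    return WeightedGraph(w)


def make_cohort_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Plain clinical table with no brain dependence (for direct model tests)."""
    data = {}
    for s in SYMPTOMS:
        for t in TIMEPOINTS:
            data[f"{s}_{t}"] = rng.normal(70, 10, n)
    data["medication_load"] = rng.gamma(2.0, 0.5, n)
    data["group"] = np.where(rng.random(n) < 0.7, "unipolar", "bipolar")
    return pd.DataFrame(data, index=pd.Index([f"s{i:03d}" for i in range(n)],
                                             name="subject_id"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture(scope="session")
def small_synth_config():
    """Modest planted-effect study conditions used across tests: 80
    subjects, 24-node 3-block connectomes, brain-term R^2 = 0.3."""
    return g.SyntheticConfig(
        n_subjects=80, n_nodes=24, n_blocks=3, effect_size=0.3, seed=20240502
    )


@pytest.fixture(scope="session")
def planted_cohort(small_synth_config):
    """One generated planted-effect cohort, shared session-wide (read-only)."""
    return g.generate_cohort(small_synth_config)
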