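"""Shared fixtures: small cohorts and random graphs, generated at test time."""

import numpy as np
import pytest

import connectoml as cm


@pytest.fixture(scope="session")
def tiny_atlas():
    return cm.default_atlas(30)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_atlas):
    """Small planted-effect cohort for fast unit-level checks."""
    plan = cm.default_effect_plan(tiny_atlas, delta=0.4)
    return cm.sample_cohort(
        tiny_atlas, plan, n_group1=10, n_group0=10, n_timepoints=120, seed=7
    )


@pytest.fixture(scope="session")
def random_graphs():
    """200 small random graphs (n <= 9) for oracle-equivalence sweeps."""
    rng = np.random.default_rng(42)
    graphs = []
    for _ in range(200):
        n = int(rng.integers(3, 10))
        p = float(rng.uniform(0.15, 0.8))
        a = (rng.random((n, n)) < p).astype(np.uint8)
        a = np.triu(a, 1)
        graphs.append(a + a.T)
    return graphs


def make_noise_table(n_per_group=20, n_features=60, seed=0):
    """Null feature table: pure Gaussian noise, balanced labels."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_group, n_features))
    y = np.array([1] * n_per_group + [0] * n_per_group)
    table = pd.DataFrame(X, columns=[f"f{i:03d}" for i in range(n_features)])
    return table, y
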