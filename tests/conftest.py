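"""Shared fixtures: small simulated datasets and fast SAEM settings."""

import numpy as np
import pandas as pd
import pytest

from trajmix import (
    SAEMSettings,
    from_frame,
    pmm_scenario,
    simulate_dataset,
    smm_scenario,
)


@pytest.fixture(scope="session")
def smm_sim():
    """One sigmoidal-scenario dataset (n=150) with its generative truth."""
    return simulate_dataset(smm_scenario(n_subjects=150, seed=42))


@pytest.fixture(scope="session")
def pmm_sim():
    """One piecewise-scenario dataset (n=150) with its generative truth."""
    return simulate_dataset(pmm_scenario(n_subjects=150, seed=42))


@pytest.fixture
def fast_settings():
    """Short SAEM schedule for tests that only need the plumbing to run."""
    return SAEMSettings(
        n_burn_iters=40, n_sa_iters=30, seed=7,
        compute_se=False, compute_loglik=False,
    )


def make_long(rows, covs=None):
    """Build a LongData from (id, time, outcome) triples."""
    df = pd.DataFrame(rows, columns=["ID", "time", "outcome"])
    if covs:
        for name, mapping in covs.items():
            df[name] = df["ID"].map(mapping)
    return from_frame(df, "ID", "outcome", "time")


@pytest.fixture
def linear_track():
    """Multi-subject noise-free data on one straight line y = 0.5 - 0.1 t."""
    rows = []
    for sid in range(1, 9):
        for t in np.linspace(-10, 0, 11):
            rows.append((sid, t, 0.5 - 0.1 * t))
    return make_long(rows)
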