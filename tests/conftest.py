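"""Shared fixtures: default tree, small synthetic datasets, EVE recovery grid.

Heavier simulations are session-scoped so several test modules can share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from noctua import EVEParams, SimConfig, fit_eve_gene, simulate_dataset, simulate_eve_data
from noctua.eve import _obs_distance_matrix
from noctua.simulate import DEFAULT_TREE
from noctua.trees import load_tree


@pytest.fixture(scope="session")
def default_tree():
    return load_tree(DEFAULT_TREE)


@pytest.fixture(scope="session")
def small_dataset():
    """150-OG dataset with the default planted effect classes, seed 1."""
    cfg = SimConfig(n_orthogroups=150)
    return cfg, simulate_dataset(cfg, seed=1)


@pytest.fixture(scope="session")
def null_dataset():
    """2000-OG dataset with no planted effects (global null), seed 11."""
    cfg = SimConfig(n_orthogroups=2000, effect_classes=[])
    return cfg, simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def eve_recovery(default_tree):
    """Median estimated beta over simulated genes, per true beta on a grid.

    Stationary-OU simulations on the default 5-species tree, 3 observations
    per species; 120 genes per grid point keeps the median stable while the
    whole grid fits in about a minute.
    """
    rng = np.random.default_rng(7)
    medians = {}
    D = None
    for beta_true in (0.1, 0.5, 1.0, 10.0, 50.0):
        params = EVEParams.from_gamma(theta=0.0, gamma=1.0, alpha=1.0, beta=beta_true)
        Y, sobs = simulate_eve_data(default_tree, params, 3, 120, rng)
        if D is None:
            D = _obs_distance_matrix(default_tree, sobs)
        betas = [
            fit_eve_gene(Y[i], default_tree, sobs, seed=i, D=D).params.beta
            for i in range(Y.shape[0])
        ]
        medians[beta_true] = float(np.median(betas))
    return medians
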