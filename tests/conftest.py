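"""Shared fixtures: simulated tissues and synthetic expression datasets.

The Lennard-Jones simulations are the expensive fixtures; they are session
scoped and shared between the simulator tests and the acceptance suite.
"""

import numpy as np
import pytest

import nichecov as nc

BENCH_SEEDS = [1, 2, 3, 4, 5]
NULL_SEEDS = [11, 12, 13, 14, 15]


def _interaction_for(snapshot, seed):
    model, graph, feat = nc.run_interaction(
        snapshot.coords, snapshot.type_labels, radius=0.0, max_dist=100.0, seed=seed
    )
    return model


@pytest.fixture(scope="session")
def scenario1_runs():
    """Five scenario-1 snapshots with fitted niche classifiers."""
    runs = []
    for seed in BENCH_SEEDS:
        snap = nc.simulate_tissue(nc.scenario_config("scenario1", seed=seed))
        runs.append((snap, _interaction_for(snap, seed)))
    return runs


@pytest.fixture(scope="session")
def scenario2_runs():
    """Five scenario-2 snapshots with fitted niche classifiers."""
    runs = []
    for seed in BENCH_SEEDS:
        snap = nc.simulate_tissue(nc.scenario_config("scenario2", seed=seed))
        runs.append((snap, _interaction_for(snap, seed)))
    return runs


@pytest.fixture(scope="session")
def null_runs():
    """Five snapshots with all affinities equal (exchangeable types)."""
    runs = []
    for seed in NULL_SEEDS:
        snap = nc.simulate_tissue(nc.SimulationConfig(seed=seed))
        runs.append((snap, _interaction_for(snap, seed)))
    return runs


@pytest.fixture(scope="session")
def quick_snapshot():
    """A cheap (short-run) snapshot where only geometry plausibility matters."""
    return nc.simulate_tissue(nc.SimulationConfig(n_steps=2000, seed=3))


@pytest.fixture(scope="session")
def synth_datasets(quick_snapshot):
    """Synthetic spatial + reference expression with known labels."""
    cfg = nc.SyntheticExpressionConfig(seed=5)
    spatial, reference, truth = nc.synth_expression(quick_snapshot, cfg)
    return spatial, reference, truth
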