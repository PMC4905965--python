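"""Shared fixtures: packaged DMN scenario data and small helper builders."""

from __future__ import annotations

import numpy as np
import pytest

import usem
from usem.simulate import SimConfig


@pytest.fixture(scope="session")
def dmn_nodes() -> list[str]:
    return [n["name"] for n in usem.load_dmn_nodes()]


@pytest.fixture(scope="session")
def dmn_edge_spec() -> dict:
    return usem.load_exploratory_edges()


@pytest.fixture(scope="session")
def dmn_edges(dmn_edge_spec) -> list[tuple[str, str]]:
    return [(e["source"], e["target"]) for e in dmn_edge_spec["edges"]]


@pytest.fixture(scope="session")
def scenario_config():
    """The packaged 13-edge DMN scenario at full study size (fixed seed)."""
    return usem.default_dmn_scenario(seed=1)


@pytest.fixture(scope="session")
def scenario_panel(scenario_config):
    return usem.simulate_panel(scenario_config)


@pytest.fixture(scope="session")
def scenario_covs(scenario_panel):
    prepped = usem.standardize(usem.censor_spikes(scenario_panel))
    return usem.cohort_covariances(usem.build_lagged(prepped))


def white_config(n_nodes=3, n_cohorts=1, subjects=4, timepoints=300, seed=0, **kw) -> SimConfig:
    """Pure white-noise generating configuration."""
    names = [f"R{i}" for i in range(n_nodes)]
    return SimConfig(
        node_names=names,
        contemporaneous=np.zeros((n_nodes, n_nodes)),
        n_cohorts=n_cohorts,
        subjects_per_cohort=subjects,
        timepoints_per_subject=timepoints,
        seed=seed,
        **kw,
    )


def lyapunov_series_oracle(M: np.ndarray, Q: np.ndarray, tol=1e-14, max_terms=100000):
    """Independent brute-force solution of Sigma = M Sigma M' + Q by
    summing the series Sigma = sum_k M^k Q (M^k)'."""
    total = Q.copy()
    term = Q.copy()
    for _ in range(max_terms):
        term = M @ term @ M.T
        total += term
        if np.abs(term).max() < tol:
            return total
    raise RuntimeError("series did not converge; process non-stationary?")
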