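import numpy as np
import pytest

import bundleflow as bf


@pytest.fixture(scope="session")
def est_cfg():
    return bf.EstimatorConfig(k=5, seed=11)


@pytest.fixture(scope="session")
def seven_var():
    """Study-scale fixture: (VARSpec, BundleSpec, simulated series)."""
    var_spec, bundles = bf.fixture_seven_var(n=2000, seed=42)
    series = bf.generate_var(var_spec)
    return var_spec, bundles, series


@pytest.fixture(scope="session")
def chain_dag():
    return bf.TimeSeriesDAG.from_edges(
        ["X", "Y", "Z"], [("X", "Y", 1), ("Y", "Z", 1)]
    )


def random_tsdag(rng, n_vars=None, max_lag=4):
    """Random stationary-template DAG for property tests."""
    n_vars = n_vars or rng.integers(2, 9)
    variables = [f"v{i}" for i in range(n_vars)]
    n_edges = int(rng.integers(1, 2 * n_vars))
    edges = set()
    for _ in range(n_edges):
        s, t = rng.choice(n_vars, size=2)
        lag = int(rng.integers(1, max_lag + 1))
        edges.add((variables[s], variables[t], lag))
    return bf.TimeSeriesDAG.from_edges(variables, sorted(edges))
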