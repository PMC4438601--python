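import numpy as np
import pytest

from netchange import AnalysisConfig, CohortSpec, ConnectomeStudy, generate_cohort


def random_weighted_graph(rng, n, p=0.5, ensure_connected=True):
    """Random symmetric weighted adjacency with zero diagonal."""
    for _ in range(200):
        mask = rng.random((n, n)) < p
        W = rng.random((n, n)) * mask
        W = np.triu(W, 1)
        W = W + W.T
        if not ensure_connected:
            return W
        # connectivity check via reachability
        reach = (W > 0).astype(int)
        power = np.eye(n, dtype=int)
        acc = np.eye(n, dtype=int)
        for _ in range(n):
            power = (power @ reach > 0).astype(int)
            acc = acc | power
        if acc.all():
            return W
    raise RuntimeError("failed to draw a connected graph")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted-effect cohort shared by model-level tests."""
    spec = CohortSpec(seed=7, n_subjects=10, n_nodes=16, n_timepoints=80,
                      n_modules=4, metric_grid=(0.2, 0.3, 0.4),
                      metric_n_rand=3)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_results(tiny_cohort):
    cfg = AnalysisConfig(seed=7, n_discard=0, sparsity_grid=(0.2, 0.3, 0.4),
                         n_rand=4, n_restarts=2, preprocess=False)
    return ConnectomeStudy.from_cohort(tiny_cohort, cfg).fit()
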