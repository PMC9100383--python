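import numpy as np
import pytest

from fractalconn import (
    MemoryParams,
    ShortMemoryCov,
    generate_two_group_study,
    simulate_multivariate_fin,
)


@pytest.fixture()
def rng():
    # fresh generator per test: draws never depend on test ordering
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def bivariate_fin():
    """One long bivariate FIN sample with known parameters.

    a = [0.3, 0.2], innovation covariance [[1, 0.6], [0.6, 1]], N = 8192.
    """
    params = MemoryParams([0.3, 0.2])
    cov = ShortMemoryCov([[1.0, 0.6], [0.6, 1.0]])
    return simulate_multivariate_fin(params, cov, 8192, seed=42), params, cov


@pytest.fixture(scope="session")
def small_study():
    """Tiny synthetic two-group study for plumbing tests (fast)."""
    return generate_two_group_study(
        n_per_group=3, v=4, N=64, effect_edges=[(0, 1)], effect_delta=0.5, seed=11
    )
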