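import numpy as np
import pytest

import catnet as cn


@pytest.fixture(scope="session")
def triangle_a():
    return cn.get_fixture("triangle_a")


@pytest.fixture(scope="session")
def triangle_b():
    return cn.get_fixture("triangle_b")


@pytest.fixture(scope="session")
def triangle_c():
    return cn.get_fixture("triangle_c")


@pytest.fixture(scope="session")
def four_species_nonergodic():
    return cn.get_fixture("four_species_nonergodic")


@pytest.fixture(scope="session")
def five_component():
    return cn.convert_2tk("five_component")


def exact_stationary(network, N, rho=1.0, epsilon=0.0, restrict_non_wta=False):
    """Brute-force stationary distribution via the generator null space."""
    params = cn.SystemParams(N=N, rho=rho, epsilon=epsilon)
    space = cn.enumerate_states(network.M, N)
    Q = cn.build_generator(network, params, space)
    restrict = space.non_wta_indices() if restrict_non_wta else None
    dists = cn.stationary_exact(Q, space, restrict_to=restrict)
    return dists, space, params


def raw_third_moments(dist, space, N):
    """Raw third concentration moments of a distribution (rho = 1)."""
    X = np.asarray(space.states, dtype=float) / N
    M = space.M
    out = {}
    for i in range(1, M + 1):
        for j in range(i, M + 1):
            for k in range(j, M + 1):
                out[(i, j, k)] = float(
                    dist.p @ (X[:, i - 1] * X[:, j - 1] * X[:, k - 1])
                )
    return out
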