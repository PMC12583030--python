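"""Shared fixtures: expensive conductance-model pipelines are session-scoped."""

import pytest

from neurodesync import (
    ControlProblem,
    find_limit_cycle,
    fit_fourier,
    hodgkin_huxley,
    reduced_hodgkin_huxley,
    solve_ocp,
)
from neurodesync.models import compute_adjoint_prc


@pytest.fixture(scope="session")
def hh_model():
    return hodgkin_huxley()


@pytest.fixture(scope="session")
def rhh_model():
    return reduced_hodgkin_huxley()


@pytest.fixture(scope="session")
def hh_lc(hh_model):
    return find_limit_cycle(hh_model)


@pytest.fixture(scope="session")
def rhh_lc(rhh_model):
    return find_limit_cycle(rhh_model)


@pytest.fixture(scope="session")
def rhh_lc_fine(rhh_model):
    # the Reduced HH adjoint has a sharp feature; resolve it on a finer grid
    return find_limit_cycle(rhh_model, M=4096)


@pytest.fixture(scope="session")
def hh_adjoint(hh_model, hh_lc):
    return compute_adjoint_prc(hh_model, hh_lc)


@pytest.fixture(scope="session")
def rhh_adjoint(rhh_model, rhh_lc_fine):
    return compute_adjoint_prc(rhh_model, rhh_lc_fine)


@pytest.fixture(scope="session")
def hh_prc(hh_adjoint, hh_lc):
    thetas, Z_V, _ = hh_adjoint
    return fit_fourier(thetas, Z_V, K=10, T=hh_lc.T)


@pytest.fixture(scope="session")
def rhh_prc(rhh_adjoint, rhh_lc_fine):
    thetas, Z_V, _ = rhh_adjoint
    return fit_fourier(thetas, Z_V, K=200, T=rhh_lc_fine.T)


@pytest.fixture(scope="session")
def ocp_cache():
    """Memoized OCP solves shared across tests (solves are deterministic)."""
    cache = {}

    def solve(prc, beta, umax, key=None):
        k = (key or id(prc), beta, umax)
        if k not in cache:
            cache[k] = solve_ocp(ControlProblem(prc=prc, beta=beta, umax=umax))
        return cache[k]

    return solve
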