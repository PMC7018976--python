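import numpy as np
import pytest

from nanobead import (
    ModelParameters,
    SolverConfig,
    continuation,
    single_domain_profiles,
    solve_shape,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def homogeneous_shape(params):
    return solve_shape(single_domain_profiles(params, sigma0=0.0), params)


@pytest.fixture(scope="session")
def protein_branch(params):
    """Continuation in protein density to σ₀ = 1.25e-4 (uniform rigidity)."""
    branch = continuation(
        np.linspace(0.0, 1.25e-4, 11),
        lambda v: single_domain_profiles(params, sigma0=float(v)),
        params,
        parameter="sigma0",
    )
    assert branch.values[-1] == pytest.approx(1.25e-4)
    return branch


@pytest.fixture(scope="session")
def protein_bead(protein_branch):
    return protein_branch.shapes[-1]


@pytest.fixture(scope="session")
def rigidity_branch(params):
    """Continuation in rigidity ratio to 30 with C = 0 and uniform composition."""
    p = params.replace(phi=0.0)
    branch = continuation(
        np.concatenate([[1.0], np.linspace(2.0, 30.0, 15)]),
        lambda k: single_domain_profiles(
            p, sigma0=1.25e-4, kappa_ratio=float(k), uniform_sigma=True
        ),
        p,
        parameter="kappa_ratio",
    )
    assert branch.values[-1] == pytest.approx(30.0)
    return branch
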