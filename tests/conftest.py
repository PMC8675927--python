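import numpy as np
import pytest

from epifold.geometry import build_hexagonal_tissue, cell_shape_summary
from epifold.mechanics import MechanicalState
from epifold.analysis import PrismShape, derive_balanced_parameters
from epifold.polarity import PolarityParams, initial_condition, \
    integrate_to_steady_state


@pytest.fixture(scope="session")
def single_prism():
    """One reference columnar cell (the default prism dimensions)."""
    return build_hexagonal_tissue(0)


@pytest.fixture(scope="session")
def reference_shape(single_prism):
    cs = cell_shape_summary(single_prism, 0)
    return PrismShape(h=cs.ell, r=cs.a, P_hat_o=2.16)


@pytest.fixture(scope="session")
def balanced_mech(reference_shape):
    """Exactly balanced mechanical parameters for the reference prism."""
    K_a, lam_b, lam_l = derive_balanced_parameters(reference_shape)
    def make(n_cells):
        return MechanicalState.uniform(n_cells, K_a=K_a, P_hat_o=2.16,
                                       lambda_b=lam_b, lambda_ell=lam_l)
    return make


@pytest.fixture(scope="session")
def reference_geometry(single_prism):
    return cell_shape_summary(single_prism, 0)


@pytest.fixture(scope="session")
def polarized_steady(reference_geometry):
    """Reference polarized steady state on the fixed columnar geometry (512 nodes)."""
    cs = reference_geometry
    params = PolarityParams()
    f = initial_condition(512, cs.L, cs.a, cs.ell, params, cs.psi)
    f, ok = integrate_to_steady_state(f, params, cs.psi, dt=0.05, tol=1e-9)
    assert ok
    return f, params, cs
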