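import numpy as np
import pytest

from dyadcausal import VARSpec, make_dyad_spec, simulate_var


@pytest.fixture(scope="session")
def planted_dyad_spec():
    """Six-variable dyad with three between-brain couplings of 0.15."""
    return make_dyad_spec(
        inter_links=[
            ("leader", "Fz", "follower", "Fz", 2, 0.15),
            ("leader", "F3", "follower", "F3", 4, 0.15),
            ("leader", "F4", "follower", "F4", 1, 0.15),
        ],
        autocorr=0.4,
    )


@pytest.fixture(scope="session")
def planted_dyad_series(planted_dyad_spec):
    return simulate_var(planted_dyad_spec, 12_400, seed=2024)


def ar1_spec(phi: float, n_vars: int = 1) -> VARSpec:
    coeffs = np.zeros((1, n_vars, n_vars))
    coeffs[0][np.diag_indices(n_vars)] = phi
    return VARSpec(coeffs=coeffs, noise_sd=np.ones(n_vars))


def white_noise_spec(n_vars: int, max_lag: int = 1) -> VARSpec:
    return VARSpec(coeffs=np.zeros((max_lag, n_vars, n_vars)), noise_sd=np.ones(n_vars))
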