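import numpy as np
import pytest

import gridforge as gf

# Published spiking-simulation configuration (square arena, place-like inputs)
FIG5_A = 1.1001904761904762  # r_av [alpha - closed-form window/kernel overlap]
FIG5_B = 0.488  # r_av (W_tot r_0 + beta)


@pytest.fixture(scope="session")
def kernel():
    return gf.AdaptationKernel(tau_s=0.1, tau_l=0.16, mu=1.06)


@pytest.fixture(scope="session")
def field_spec():
    return gf.GaussianFieldSpec(sigma=0.0625, r_av=0.4, L=1.0)


@pytest.fixture(scope="session")
def plasticity():
    return gf.PlasticityParams(eta=2e-5, tau_w=0.05, w_tot=1.0, alpha=3.56, beta=-8.78)


@pytest.fixture(scope="session")
def neuron():
    return gf.NeuronParams(r_0=10.0, dt=1e-3)


@pytest.fixture(scope="session")
def regular_ensemble_900(field_spec):
    return gf.make_regular_ensemble(900, field_spec)


@pytest.fixture(scope="session")
def correlation_900(regular_ensemble_900, kernel):
    """Discrete correlation matrix of the published N=900, L=1 configuration."""
    return gf.correlation_matrix(regular_ensemble_900, kernel, v=0.25, w_tot=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
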