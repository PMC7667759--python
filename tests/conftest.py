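import pytest

from sivs import CompartmentState, ModelParams

# Worked parameter set used throughout: q=0.4, p=0.2, gamma=0.15, mu=0.1,
# eps=0.25, with initial compartments (I, S, V) = (0.4, 0.8, 0.5), N = 1.7.


@pytest.fixture
def disc_params():
    """Worked parameter set at beta=0.4 (R0 < 1)."""
    return ModelParams(mu=0.1, beta=0.4, gamma=0.15, epsilon=0.25, p=0.2, q=0.4, N=1.7)


@pytest.fixture
def disc_init():
    return CompartmentState(I=0.4, S=0.8, V=0.5, t=0)


@pytest.fixture
def disc_init_reduced():
    return (0.4, 0.8)
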