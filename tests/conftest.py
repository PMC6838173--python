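import pytest

from crdgame import DynamicsParams, GameParams


@pytest.fixture
def baseline_params() -> GameParams:
    """High-threshold baseline: Z=50, N=10, M=5, c=0.1, B=1, r=0.5."""
    return GameParams(Z=50, N=10, M=5, B=1.0, c=0.1, r=0.5)


@pytest.fixture
def low_threshold_params() -> GameParams:
    """Low relative threshold M/N = 3/10 used in the risk sweeps."""
    return GameParams(Z=50, N=10, M=3, B=1.0, c=0.1, r=0.5)


@pytest.fixture
def dyn() -> DynamicsParams:
    return DynamicsParams(beta=5.0, mu=0.01)
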