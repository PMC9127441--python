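import numpy as np
import pytest

from neqprf import GammaDFE, PDEEngine


@pytest.fixture(scope="session")
def dfe() -> GammaDFE:
    """Default purifying-selection DFE: shape 0.15, mean strength 2500."""
    return GammaDFE.from_mean(0.15, 2500.0)


@pytest.fixture(scope="session")
def pde_engine() -> PDEEngine:
    """Shared deterministic engine (memoizes tables across tests)."""
    return PDEEngine()


@pytest.fixture(scope="session")
def pde_engine_fast() -> PDEEngine:
    """Coarser engine for sweep-style tests."""
    return PDEEngine(ny=1001)


@pytest.fixture(autouse=True)
def _seed_numpy():
    np.random.seed(0)
    yield
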