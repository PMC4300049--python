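import numpy as np
import pytest

from lcrgene.thermo import EnergyModel, load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def model(params):
    """Shared folding context (warm numba kernel, shared pair cache)."""
    m = EnergyModel(params)
    m.cofold("ACGT", "ACGT")  # trigger JIT compilation once
    return m


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
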