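import numpy as np
import pytest

import pscea


@pytest.fixture(scope="session")
def itt():
    """Packaged ITT inputs (spec, settings)."""
    return pscea.builtin_choice01("ITT")


@pytest.fixture(scope="session")
def itt_fit(itt):
    spec, settings = itt
    return pscea.CostEffectivenessModel(spec, settings).fit()


@pytest.fixture(scope="session")
def all_populations():
    return {pop: pscea.builtin_choice01(pop) for pop in pscea.POPULATIONS}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
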