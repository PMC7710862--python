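import numpy as np
import pytest

from mimicolor import fixtures
from mimicolor.colorspace import VisualSystem


@pytest.fixture(scope="session")
def disc_fns():
    """Published discrimination functions (successive blue/yellow, absolute)."""
    return fixtures.discrimination_functions()


@pytest.fixture(scope="session")
def pdfs():
    """The four published flower-colour PDFs."""
    return fixtures.flower_pdfs()


@pytest.fixture(scope="session")
def bee_vs():
    return VisualSystem.honeybee()


@pytest.fixture()
def rng():
    return np.random.default_rng(20201119)
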