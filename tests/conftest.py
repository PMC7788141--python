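import numpy as np
import pytest

from petqc import listmode
from petqc.presets import load_preset


@pytest.fixture(scope="session")
def vereos():
    return load_preset("vereos")


@pytest.fixture(scope="session")
def ingenuity():
    return load_preset("ingenuity")


@pytest.fixture(scope="session")
def scatter_phantom():
    return listmode.PhantomSpec()


@pytest.fixture(scope="session")
def lm_trues(vereos, scatter_phantom):
    """Trues-only recording at a low rate: every event annihilates on the
    line source, timing blur is the preset's 326-ps FWHM."""
    pure = listmode.trues_only_preset(vereos)
    return listmode.sample_coincidences(pure, scatter_phantom, 2.0, 300_000,
                                        seed=11, duration_s=400.0)


@pytest.fixture(scope="session")
def lm_mixed(vereos, scatter_phantom):
    """Recording with the full true/scatter/random mixture at a high rate."""
    return listmode.sample_coincidences(vereos, scatter_phantom, 20.0, 150_000,
                                        seed=12, duration_s=300.0)
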