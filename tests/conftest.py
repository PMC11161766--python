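import numpy as np
import pytest

from phasecode import ModelConfig, build_connectivity, build_lexicon
from phasecode.protocols import MorphSpectrum, STUDY_SPECTRA


@pytest.fixture(scope="session")
def lexicon():
    return build_lexicon()


@pytest.fixture(scope="session")
def connectivity(lexicon):
    return build_connectivity(lexicon, "parallel")


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def consonant_spectrum():
    """/xɑt/-/dɑt/: both traits favor the /dɑt/ endpoint."""
    return MorphSpectrum(*STUDY_SPECTRA[1])


@pytest.fixture(scope="session")
def balanced_spectrum():
    """/xat/-/dat/: trait advantages oppose across levels."""
    return MorphSpectrum(*STUDY_SPECTRA[0])
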