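import numpy as np
import pytest

from pepperpot.geometry import (
    OpticalMedia,
    default_media,
    dorsal_geometry,
    ventral_geometry,
)
from pepperpot.pipeline import VaporResponseModel


@pytest.fixture(scope="session")
def media():
    return default_media()


@pytest.fixture(scope="session")
def lossless_media():
    return OpticalMedia(n_chitin=1.56 + 0j)


@pytest.fixture(scope="session")
def dorsal():
    return dorsal_geometry()


@pytest.fixture(scope="session")
def ventral():
    return ventral_geometry()


@pytest.fixture(scope="session")
def dorsal_model(dorsal):
    return VaporResponseModel(dorsal)


@pytest.fixture(scope="session")
def ventral_model(ventral):
    return VaporResponseModel(ventral)


@pytest.fixture
def rng():
    return np.random.default_rng(20190517)
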