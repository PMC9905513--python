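import numpy as np
import pytest

from artefactscan.matching import TemplatePattern
from artefactscan.synth import make_template


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_template():
    return TemplatePattern(make_template(7, shape=(8, 9), sigma=1.5), "tiny")
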