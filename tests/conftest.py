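import numpy as np
import pytest

from fdeam.scar_scores import MB, ChromosomeAnnotation
from fdeam.synthetic_cohort import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_annotation():
    """One 100 Mb chromosome with a centromere at 45-48 Mb."""
    return {"chr1": ChromosomeAnnotation(100 * MB, 45 * MB, 48 * MB)}


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20+20 synthetic cohort, shared across read-only tests."""
    return generate_cohort(GeneratorConfig(seed=11))
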