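import numpy as np
import pytest

from dehprecon.constants import METABOLITES
from dehprecon.dose_recon import FitConfig
from dehprecon.pk_forward import Subject, default_specs


@pytest.fixture(scope="session")
def specs4():
    return default_specs()


@pytest.fixture(scope="session")
def subject70():
    return Subject(id="S1", sex="M")


@pytest.fixture()
def fitcfg_nolod():
    """Fit configuration with LOD imputation disabled (noise-free fixtures)."""
    return FitConfig(lod={m: 0.0 for m in METABOLITES})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
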