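import numpy as np
import pytest

from mmp2d.mmp_core import MmpConfig
from mmp2d.semg_matrix import SemgRecord
from mmp2d.synthetic import SynthSpec, gen_isometric


@pytest.fixture(scope="session")
def desk_config() -> MmpConfig:
    """Small dictionary cap keeps desk-scale runs fast; the codec's
    correctness properties (losslessness, synchronization) do not depend on
    the cap."""
    return MmpConfig(dict_cap=512)


@pytest.fixture(scope="session")
def iso_record() -> SemgRecord:
    """A short seeded isometric synthetic record (1000 samples at 2 kHz)."""
    return gen_isometric(SynthSpec(protocol="isometric", duration_s=0.5, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
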