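import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from cibalance.cohort import packaged_cohort
from cibalance.montage import standard_62_montage
from cibalance.source_imaging import build_head_model, compute_leadfield


@pytest.fixture(scope="session")
def head():
    return build_head_model()


@pytest.fixture(scope="session")
def montage62(head):
    names, chan_pos, ref_pos = standard_62_montage(head.scalp_radius)
    return names, chan_pos, ref_pos


@pytest.fixture(scope="session")
def leadfield10(head, montage62):
    """10 mm grid lead field shared by the beamformer tests."""
    _, chan_pos, _ = montage62
    return compute_leadfield(head, 10.0, chan_pos, reference="none")


@pytest.fixture(scope="session")
def leadfield20(head, montage62):
    """Coarse 20 mm grid for fast calibration tests."""
    _, chan_pos, _ = montage62
    return compute_leadfield(head, 20.0, chan_pos, reference="none")


@pytest.fixture(scope="session")
def cohort13():
    return packaged_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
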