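import numpy as np
import pytest

from eegraph.montage import CHANNELS
from eegraph.preprocess import EpochSet, Recording
from eegraph.synthetic import CohortSpec, null_cohort_spec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def white_recording(rng):
    """19-channel white-noise recording, 30 s at 200 Hz."""
    data = 5.0 * rng.standard_normal((19, 6000))
    return Recording(CHANNELS, 200.0, data, subject_id="w00", group="HC")


@pytest.fixture
def small_epochs(rng):
    """10 white-noise epochs of 2 s at 200 Hz."""
    eps = rng.standard_normal((10, 19, 400))
    return EpochSet(eps, CHANNELS, 200.0, 2.0, subject_id="e00")


@pytest.fixture
def tiny_cohort_spec() -> CohortSpec:
    """Small, fast null cohort for pipeline-level tests."""
    spec = null_cohort_spec(n_hc=3, n_mci=3, duration=14.0, seed=11)
    return spec


def random_adjacency(n, p, seed):
    """Random symmetric 0/1 adjacency without self-loops."""
    rng = np.random.default_rng(seed)
    a = rng.random((n, n)) < p
    a = np.triu(a, k=1)
    a = a | a.T
    return a.astype(int)
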