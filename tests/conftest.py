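import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from voltkit import CvSpec, DpvSpec, Mode, Voltammogram, simulate_cv, \
    simulate_dpv


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def dpv_trace():
    """A default-conditions synthetic DPV trace with its ground truth."""
    return simulate_dpv(DpvSpec(seed=7))


@pytest.fixture
def cv_trace():
    """A default-conditions synthetic CV trace with its ground truth."""
    return simulate_cv(CvSpec(seed=7))


@pytest.fixture
def clean_cv_trace():
    return simulate_cv(CvSpec(seed=7, noise_sigma=0.0))


def make_voltammogram(potentials, currents, mode=Mode.DPV, **kwargs):
    return Voltammogram(np.asarray(potentials, float),
                        np.asarray(currents, float), mode=mode, **kwargs)
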