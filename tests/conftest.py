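import numpy as np
import pytest

from toolgaze.design import DesignParams, build_schedule
from toolgaze.gaze_io import GazeTrace
from toolgaze.simulate import (KinematicsParams, LatencyModel,
                               NoiseAndArtifactParams)


@pytest.fixture(scope="session")
def default_params():
    return DesignParams()


@pytest.fixture(scope="session")
def default_schedule(default_params):
    return build_schedule(default_params)


@pytest.fixture(scope="session")
def small_params():
    """A 1-block miniature of the session keeping all four conditions."""
    return DesignParams(n_blocks=1, trials_per_block=20, n_head=8,
                        n_handle=8, n_control=2, n_red=2)


@pytest.fixture
def kinematics():
    return KinematicsParams()


@pytest.fixture
def fixed_latency():
    """Deterministic latency model: every draw is exactly 400 ms."""
    return LatencyModel.null(mean=400.0, subject_sd=0.0, trial_sd=0.0,
                             exgauss_tau=0.0)


@pytest.fixture
def clean_noise():
    return NoiseAndArtifactParams.clean()


def make_trace(x, y=None, missing=None, sample_rate=300.0):
    """Build a degree-unit GazeTrace from plain arrays."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    if missing is None:
        missing = np.zeros(len(x), dtype=bool)
    t = np.arange(len(x)) * (1000.0 / sample_rate)
    return GazeTrace(t, x.copy(), y.copy(), np.asarray(missing, bool).copy(),
                     unit="deg", sample_rate=sample_rate)
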