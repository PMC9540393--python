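import numpy as np
import pytest

from leica.io import RegionalTimeSeries
from leica.synthetic import SynthSpec, synth_phase_communities


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten 10-region subjects with three planted phase communities."""
    spec = SynthSpec(
        n_regions=10, n_timepoints=120, tr=2.0, n_subjects_per_group=10,
        n_communities=3, coupling_strength=1.0, noise_sd=0.25, seed=7,
    )
    return synth_phase_communities(spec)


@pytest.fixture()
def sine_ts():
    """Two-region 0.05 Hz cosine/sine pair sampled at tr = 2 s."""
    tr = 2.0
    t = np.arange(600) * tr
    return RegionalTimeSeries(
        values=np.vstack([np.cos(2 * np.pi * 0.05 * t), np.sin(2 * np.pi * 0.05 * t)]),
        tr=tr,
    )
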