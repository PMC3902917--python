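import numpy as np
import pytest

from plasmidyn.synth import TrajectoryGenSpec, gen_confined_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def confined_track():
    """One noise-free confined track at study-scale parameters."""
    spec = TrajectoryGenSpec(D=2.5e-3, box_long=0.43, box_short=0.4,
                             dt=10.0, n_steps=150, loc_noise_sd=0.0, seed=7)
    return gen_confined_trajectory(spec)
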