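import numpy as np
import pytest

from mnreflex.inputs import StimulusTrain, generate_stimulus_train
from mnreflex.pool import MNParameters, build_pool, reference_rheobase
from mnreflex.spikestats import SpikeTrain
from mnreflex.surrogate import SurrogateConfig, renewal_train


@pytest.fixture(scope="session")
def reference_neuron() -> MNParameters:
    """Unit-size reference neuron."""
    return MNParameters(index=1, size_factor=1.0, target_rheobase_nA=1.0)


@pytest.fixture(scope="session")
def ref_rheobase() -> float:
    return reference_rheobase()


@pytest.fixture(scope="session")
def default_pool():
    """The full calibrated 200-neuron pool."""
    return build_pool()


@pytest.fixture(scope="session")
def small_pool():
    """A 50-neuron pool for cheaper pool-level checks."""
    return build_pool(n_mns=50)


@pytest.fixture()
def stimuli_200() -> StimulusTrain:
    return generate_stimulus_train(count=200, seed=7)


@pytest.fixture()
def periodic_train_10hz() -> SpikeTrain:
    """Perfectly periodic 10 Hz train over 220 s."""
    times = np.arange(100.0, 219_000.0, 100.0)
    return SpikeTrain(times, 220_000.0, source="surrogate")


@pytest.fixture()
def background_train() -> SpikeTrain:
    """Irregular renewal train (10 Hz, 15% CoV) over 220 s."""
    cfg = SurrogateConfig(dr_hz=10.0, cov_isi_pct=15.0, duration_ms=220_000.0, seed=3)
    return renewal_train(cfg)
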