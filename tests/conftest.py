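import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def warm_numba():
    """Compile the numba kernels once up front so timings don't skew tests."""
    from cbnsim.conductance import ConductanceTrace, ipsg_kernel, convolve_train
    from cbnsim.neuron import RATE_PRESET, simulate, simulate_streaming
    from cbnsim.spike_gen import SpikeTrain
    import numpy as np

    train = SpikeTrain(np.array([0.001]), 0.01)
    convolve_train(train, ipsg_kernel(), 0.01)
    n = 501
    simulate(RATE_PRESET,
             ConductanceTrace(0.02, np.zeros(n)),
             ConductanceTrace(0.02, np.zeros(n)))
    simulate_streaming(RATE_PRESET, np.array([1.0]), np.array([1.0]), 0.01,
                       1000.0, np.random.default_rng(0))
    return True
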