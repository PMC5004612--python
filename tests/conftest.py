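import numpy as np
import pytest

from respiro import ImpulseResponse, TimeSeries, forward_convolve


@pytest.fixture
def rng():
    return np.random.default_rng(20160721)


@pytest.fixture
def exp_kernel():
    """Unit-area exponential washout kernel, support 30, no delay."""
    h = np.exp(-np.arange(30) / 6.0)
    return ImpulseResponse(0.1, h / h.sum(), n0_delay=0)


@pytest.fixture
def delayed_kernel():
    """Unit-area kernel with a 10-sample transport delay, support 40."""
    h = np.concatenate([np.zeros(10), np.exp(-np.arange(30) / 6.0)])
    return ImpulseResponse(0.1, h / h.sum(), n0_delay=10)


@pytest.fixture
def pulse_record(exp_kernel):
    """Noiseless pulse-train input and its measured output, N=2000."""
    from respiro import PulseTrainConfig, synth_pulse_train

    u = synth_pulse_train(PulseTrainConfig(frequency=0.5, n_pulses=3,
                                           start_time=5.0), 2000, 0.1)
    return u, forward_convolve(u, exp_kernel)
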