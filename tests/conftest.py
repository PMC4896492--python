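import numpy as np
import pytest

from gammatopo.bga import TrialEpochSet


def tone_epochs(freq_hz=80.0, amplitude=1.0, fs=1000.0, n_trials=3,
                window=(-1.0, 1.0), phase=0.0):
    """Pure-tone epoch set (closed-form oracle: envelope == amplitude)."""
    t0, t1 = window
    t = t0 + np.arange(int(round((t1 - t0) * fs))) / fs
    v = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return TrialEpochSet(voltages=np.tile(v, (n_trials, 1)), time_axis=t,
                         sampling_rate_hz=fs,
                         categories=np.array(["a"] * n_trials),
                         electrode_id="tone")


def noise_epochs(rng, fs=1000.0, n_trials=4, window=(-1.0, 1.0), sd=1.0,
                 labels=None):
    t0, t1 = window
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs
    if labels is None:
        labels = np.array(["a"] * n_trials)
    return TrialEpochSet(voltages=rng.standard_normal((n_trials, n)) * sd,
                         time_axis=t, sampling_rate_hz=fs,
                         categories=np.asarray(labels), electrode_id="noise")


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so outcomes
    # cannot depend on test execution order
    return np.random.default_rng(12345)
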