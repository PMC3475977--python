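"""Shared fixtures: programmatically generated oscillatory trials."""

import numpy as np
import pytest

from clusterphase import MovementTimeSeries, PhaseTimeSeries, wrap_angle


def make_sinusoid_trial(freqs, sample_rate=60.0, duration=60.0, phases=None, amplitudes=None):
    """Stack pure sinusoid channels cos(2*pi*f*t + phase) into a trial."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    n = freqs.size
    t = np.arange(int(round(sample_rate * duration))) / sample_rate
    phases = np.zeros(n) if phases is None else np.asarray(phases, dtype=float)
    amplitudes = np.ones(n) if amplitudes is None else np.asarray(amplitudes, dtype=float)
    values = amplitudes[:, None] * np.cos(2 * np.pi * freqs[:, None] * t + phases[:, None])
    return MovementTimeSeries(values, sample_rate=sample_rate)


def make_phase_series(phases, sample_rate=60.0):
    """Wrap raw (n, N) angles into a PhaseTimeSeries."""
    return PhaseTimeSeries(wrap_angle(np.asarray(phases, dtype=float)),
                           sample_rate=sample_rate, method_tag="synthetic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def six_identical():
    """Six identical 0.6 Hz sinusoids, 60 Hz, 60 s."""
    return make_sinusoid_trial([0.6] * 6)


@pytest.fixture
def five_plus_odd():
    """Five 0.6 Hz channels plus one incommensurate 0.73 Hz channel, 300 s."""
    return make_sinusoid_trial([0.6] * 5 + [0.73], duration=300.0)
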