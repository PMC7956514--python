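import numpy as np
import pytest

from facevitals import SampledSignal


@pytest.fixture
def tone():
    """Factory for pure sinusoid test signals."""

    def _tone(freq_hz: float, fs: float, duration_s: float, amplitude: float = 1.0,
              phase: float = 0.0) -> SampledSignal:
        t = np.arange(int(round(duration_s * fs))) / fs
        return SampledSignal(amplitude * np.sin(2 * np.pi * freq_hz * t + phase), fs)

    return _tone


def steady_state_amplitude(values: np.ndarray, edge_trim: int) -> float:
    """Peak amplitude of an oscillation, excluding filter edge transients."""
    core = values[edge_trim:-edge_trim] if edge_trim else values
    return float(np.max(np.abs(core)))
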