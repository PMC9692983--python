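import numpy as np
import pytest

from breathsense.protocol import default_protocol, synth_protocol


@pytest.fixture(scope="session")
def ref_protocol():
    """The default twelve-segment reference protocol at 10 Hz."""
    return synth_protocol(default_protocol())


@pytest.fixture(scope="session")
def protocol_specs():
    return default_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sine_signal(rr_bpm: float, re_nu: float = 1.0, duration_s: float = 60.0, fs: float = 10.0):
    """Plain sinusoidal breathing segment used across tests."""
    t = np.arange(int(round(duration_s * fs))) / fs
    return re_nu * np.sin(2 * np.pi * rr_bpm / 60.0 * t)


def measure_rr(x, fs: float = 10.0) -> float:
    """Median breath rate from parabolic-refined peak intervals.

    Peak criteria scale with the signal (40 % of its 99th-percentile
    magnitude, spacing >= 1.2 s) so sensor noise never counts as breaths.
    Serves as the independent rate oracle for augmentation checks.
    """
    from scipy.signal import find_peaks

    x = np.asarray(x, dtype=float)
    floor = 0.4 * np.percentile(np.abs(x), 99)
    peaks, _ = find_peaks(x, prominence=max(floor, 1e-9), distance=int(1.2 * fs))
    if len(peaks) < 2:
        return float("nan")
    t = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(x) - 1)
    pi = peaks[inner]
    denom = x[pi - 1] - 2 * x[pi] + x[pi + 1]
    ok = denom < -1e-12
    shift = np.zeros(len(pi))
    shift[ok] = 0.5 * (x[pi - 1] - x[pi + 1])[ok] / denom[ok]
    t[inner] += np.clip(shift, -0.5, 0.5)
    return 60.0 / (np.median(np.diff(t)) / fs)
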