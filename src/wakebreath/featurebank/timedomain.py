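"""Time-domain amplitude/regularity descriptors of a breath phase."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps


def zero_crossing_rate(x: np.ndarray, fs: float) -> float:
    """Sign changes per second."""
    x = np.asarray(x, dtype=float)
    s = np.signbit(x)
    return float(np.count_nonzero(s[1:] != s[:-1]) / (x.size / fs))


def waveform_length(x: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(np.asarray(x, dtype=float)))))


def _cycle_peaks(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle peak locations/amplitudes at the dominant periodicity."""
    x = np.asarray(x, dtype=float)
    ac = sps.correlate(x, x, mode="full")[x.size - 1:]
    ac = ac / max(ac[0], 1e-300)
    # dominant period: first local max of autocorrelation past the first zero
    zero = np.flatnonzero(ac < 0)
    start = zero[0] if zero.size else 1
    if start >= ac.size - 1:
        return np.array([]), np.array([])
    lag = start + int(np.argmax(ac[start:]))
    lag = max(lag, 2)
    peaks, _ = sps.find_peaks(x, distance=max(int(0.7 * lag), 1))
    return peaks.astype(float), x[peaks.astype(int)]


def jitter_shimmer(x: np.ndarray, fs: float) -> tuple[float, float]:
    """Relative cycle-to-cycle period (jitter) and amplitude (shimmer) perturbation.

    Both are mean absolute consecutive differences normalized by the mean, on
    the peak sequence at the dominant periodicity; 0 for perfectly periodic
    signals, NaN when fewer than 3 cycles are found.
    """
    locs, amps = _cycle_peaks(x, fs)
    if locs.size < 3:
        return float("nan"), float("nan")
    periods = np.diff(locs)
    jitter = float(np.mean(np.abs(np.diff(periods))) / max(np.mean(periods), 1e-300))
    shimmer = float(np.mean(np.abs(np.diff(amps))) / max(np.mean(np.abs(amps)), 1e-300))
    return jitter, shimmer


def noise_to_harmonic_ratio(x: np.ndarray) -> float:
    """NHR from the normalized autocorrelation peak at the dominant lag.

    The autocorrelation maximum r at a non-zero lag estimates the harmonic
    (periodic) energy fraction; NHR = (1 - r)/r, 0 for a pure periodic
    signal and large for noise.
    """
    x = np.asarray(x, dtype=float)
    ac = sps.correlate(x, x, mode="full")[x.size - 1:]
    ac = ac / max(ac[0], 1e-300)
    zero = np.flatnonzero(ac < 0)
    start = zero[0] if zero.size else 1
    if start >= ac.size - 1:
        return float("inf")
    r = float(np.max(ac[start:]))
    r = min(max(r, 1e-6), 1.0)
    return (1.0 - r) / r


def amplitude_modulation_depth(x: np.ndarray, fs: float, smooth_ms: float = 50.0) -> float:
    """(max - min)/(max + min) of the smoothed magnitude envelope."""
    x = np.abs(sps.hilbert(np.asarray(x, dtype=float)))
    win = max(int(smooth_ms * fs / 1000.0), 1)
    env = np.convolve(x, np.ones(win) / win, mode="valid")
    if env.size == 0:
        return float("nan")
    mx, mn = float(np.max(env)), float(np.min(env))
    return (mx - mn) / max(mx + mn, 1e-300)


def time_features(x: np.ndarray, fs: float, prefix: str = "") -> dict[str, float]:
    """Bundle of time-domain descriptors for one phase."""
    x = np.asarray(x, dtype=float)
    jit, shim = jitter_shimmer(x, fs)
    ac = sps.correlate(x, x, mode="full")[x.size - 1:]
    ac = ac / max(ac[0], 1e-300)
    zero = np.flatnonzero(ac < 0)
    return {
        prefix + "zcr": zero_crossing_rate(x, fs),
        prefix + "rms": float(np.sqrt(np.mean(x**2))),
        prefix + "energy": float(np.sum(x**2)),
        prefix + "waveform_length": waveform_length(x),
        prefix + "jitter": jit,
        prefix + "shimmer": shim,
        prefix + "nhr": noise_to_harmonic_ratio(x),
        prefix + "autocorr_lag1": float(ac[1]) if ac.size > 1 else float("nan"),
        prefix + "autocorr_first_zero": float(zero[0] / fs) if zero.size else float("nan"),
        prefix + "am_depth": amplitude_modulation_depth(x, fs),
    }
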