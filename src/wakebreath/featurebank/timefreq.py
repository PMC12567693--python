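"""Time-frequency features: MFCC, wavelet sub-bands, CQT, TQWT and HPSS.

All transforms are implemented here from their standard definitions on top of
numpy/scipy/PyWavelets:

* MFCC — framed power spectrum, HTK-style mel filterbank, log, orthonormal
  DCT-II; per-coefficient mean/SD/skew across frames.
* Wavelet sub-bands — orthogonal DWT (db4, periodization mode) whose band
  energies sum exactly to the signal energy (Parseval).
* CQT — windowed DFT filterbank at geometrically spaced center frequencies
  with constant Q.
* TQWT — tunable Q-factor wavelet transform (two-channel frequency-domain
  filter bank with Daubechies transition functions); a tight frame, so
  sub-band energies conserve total energy.
* HPSS — harmonic/percussive split by median filtering the STFT magnitude
  along time vs frequency.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage
from scipy import signal as sps
from scipy.fft import dct
from scipy.stats import kurtosis, skew

# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, nfft//2 + 1)."""
    fmax = fmax or fs / 2
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((nfft + 1) * hz_pts / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(1, n_filters + 1):
        l, c, r = bins[i - 1], bins[i], bins[i + 1]
        for k in range(l, c):
            if c > l:
                fb[i - 1, k] = (k - l) / (c - l)
        for k in range(c, r):
            if r > c:
                fb[i - 1, k] = (r - k) / (r - c)
    return fb


def mfcc(x: np.ndarray, fs: float, n_coeffs: int = 13, n_filters: int = 26,
         frame_ms: float = 25.0, hop_ms: float = 10.0) -> np.ndarray:
    """MFCC matrix (n_frames, n_coeffs)."""
    x = np.asarray(x, dtype=float)
    frame = int(frame_ms * fs / 1000.0)
    hop = int(hop_ms * fs / 1000.0)
    if x.size < frame:
        raise ValueError("signal shorter than one MFCC frame")
    n_frames = (x.size - frame) // hop + 1
    win = np.hamming(frame)
    nfft = int(2 ** np.ceil(np.log2(frame)))
    fb = mel_filterbank(n_filters, nfft, fs)
    coeffs = np.empty((n_frames, n_coeffs))
    for i in range(n_frames):
        seg = x[i * hop: i * hop + frame] * win
        ps = np.abs(np.fft.rfft(seg, nfft)) ** 2 / nfft
        mel = np.log(np.maximum(fb @ ps, 1e-30))
        coeffs[i] = dct(mel, type=2, norm="ortho")[:n_coeffs]
    return coeffs


def mfcc_features(x: np.ndarray, fs: float, n_coeffs: int = 13,
                  prefix: str = "") -> dict[str, float]:
    """Mean/SD/skew of each MFCC coefficient across frames."""
    c = mfcc(x, fs, n_coeffs=n_coeffs)
    out: dict[str, float] = {}
    sds = c.std(axis=0)
    sk = skew(c, axis=0)
    for j in range(n_coeffs):
        out[f"{prefix}mfcc{j}_mean"] = float(c[:, j].mean())
        out[f"{prefix}mfcc{j}_sd"] = float(sds[j])
        out[f"{prefix}mfcc{j}_skew"] = float(sk[j]) if c.shape[0] > 2 else 0.0
    return out


# ---------------------------------------------------------------------------
# wavelet sub-bands (orthogonal DWT)
# ---------------------------------------------------------------------------


def wavelet_band_energies(x: np.ndarray, wavelet: str = "db4",
                          level: int = 5) -> np.ndarray:
    """Per-band energies [cA_L, cD_L, ..., cD_1]; sums to signal energy."""
    coeffs = pywt.wavedec(np.asarray(x, dtype=float), wavelet, mode="periodization",
                          level=level)
    return np.array([float(np.sum(c**2)) for c in coeffs])


def wavelet_features(x: np.ndarray, fs: float, wavelet: str = "db4",
                     level: int = 5, prefix: str = "") -> dict[str, float]:
    """Band energies (fractions), wavelet entropy, and energy-weighted
    spectral bandwidth/kurtosis over the dyadic band center frequencies."""
    e = wavelet_band_energies(x, wavelet, level)
    total = float(np.sum(e))
    p = e / total if total > 0 else np.full_like(e, 1.0 / e.size)
    # band center freqs: approximation fc_k for [cA_L, cD_L..cD_1]
    centers = [fs / 2 ** (level + 2)]
    centers += [3 * fs / 2 ** (j + 2) for j in range(level, 0, -1)]
    centers = np.array(centers)
    mu = float(np.sum(p * centers))
    bw = float(np.sqrt(np.sum(p * (centers - mu) ** 2)))
    kur = float(np.sum(p * ((centers - mu) / max(bw, 1e-300)) ** 4)) if bw > 0 else 0.0
    ent = float(-np.sum(p[p > 0] * np.log(p[p > 0])) / np.log(p.size))
    out = {f"{prefix}wav_band{j}_frac": float(p[j]) for j in range(p.size)}
    out[f"{prefix}wav_total_energy"] = total
    out[f"{prefix}wav_entropy"] = ent
    out[f"{prefix}wav_bandwidth"] = bw
    out[f"{prefix}wav_kurtosis"] = kur
    return out


# ---------------------------------------------------------------------------
# constant-Q transform
# ---------------------------------------------------------------------------


def cqt_band_energies(x: np.ndarray, fs: float, fmin: float = 100.0,
                      n_bins: int = 48, bins_per_octave: int = 12,
                      hop_s: float = 0.05) -> np.ndarray:
    """Mean squared magnitude per CQT bin via windowed DFT kernels."""
    x = np.asarray(x, dtype=float)
    q = 1.0 / (2 ** (1.0 / bins_per_octave) - 1.0)
    energies = np.zeros(n_bins)
    hop = max(int(hop_s * fs), 1)
    for k in range(n_bins):
        fk = fmin * 2 ** (k / bins_per_octave)
        if fk >= fs / 2:
            break
        nk = min(int(np.ceil(q * fs / fk)), x.size)
        if nk < 8:
            continue
        t = np.arange(nk)
        kernel = np.hanning(nk) * np.exp(-2j * np.pi * fk * t / fs) / nk
        starts = np.arange(0, x.size - nk + 1, hop)
        if starts.size == 0:
            continue
        mags = [np.abs(np.dot(x[s: s + nk], kernel)) for s in starts]
        energies[k] = float(np.mean(np.square(mags)))
    return energies


def cqt_features(x: np.ndarray, fs: float, prefix: str = "") -> dict[str, float]:
    e = cqt_band_energies(x, fs)
    total = float(np.sum(e))
    p = e / total if total > 0 else np.full_like(e, 1.0 / e.size)
    ent = float(-np.sum(p[p > 0] * np.log(p[p > 0])) / np.log(p.size))
    centroid_bin = float(np.sum(p * np.arange(p.size)))
    return {
        prefix + "cqt_entropy": ent,
        prefix + "cqt_centroid_bin": centroid_bin,
        prefix + "cqt_peak_bin": float(np.argmax(e)),
        prefix + "cqt_total_energy": total,
    }


# ---------------------------------------------------------------------------
# tunable Q-factor wavelet transform (TQWT)
# ---------------------------------------------------------------------------


def _tqwt_theta(w: np.ndarray) -> np.ndarray:
    """Daubechies transition function on [0, pi]: 2-regular, power complementary."""
    return 0.5 * (1 + np.cos(w)) * np.sqrt(2 - np.cos(w))


def _tqwt_channel_responses(w: np.ndarray, alpha: float, beta: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """One-level low/high responses H0, H1 on a (scaled) radian grid |w|.

    H0 = 1 below (1-beta)pi, 0 from alpha*pi; H1 is the power-complementary
    partner; both use the Daubechies transition function, so
    |H0|^2 + |H1|^2 = 1 wherever |w| <= pi.
    """
    h0 = np.zeros_like(w)
    h1 = np.zeros_like(w)
    inband = w <= np.pi
    pass_low = inband & (w < (1 - beta) * np.pi)
    stop_low = inband & (w >= alpha * np.pi)
    trans = inband & ~(pass_low | stop_low)
    h0[pass_low] = 1.0
    h0[trans] = _tqwt_theta((w[trans] + (beta - 1) * np.pi) / (alpha + beta - 1))
    h1[stop_low] = 1.0
    h1[trans] = _tqwt_theta((alpha * np.pi - w[trans]) / (alpha + beta - 1))
    return h0, h1


def tqwt_band_energies(x: np.ndarray, q: float = 2.0, redundancy: float = 3.0,
                       levels: int = 6) -> np.ndarray:
    """Sub-band energies of the TQWT: [d_1, ..., d_J, a_J].

    Undecimated frequency-domain formulation of the tunable-Q two-channel
    filter bank with beta = 2/(Q+1), alpha = 1 - beta/r: the level-j
    high-pass response is H1(w / alpha^(j-1)) times the cascade of earlier
    low-pass responses. The channel pairs are power complementary, so the
    band energies sum exactly to the signal energy (Parseval).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    beta = 2.0 / (q + 1.0)
    alpha = 1.0 - beta / redundancy
    w = np.abs(np.fft.fftfreq(n)) * 2 * np.pi
    X2 = np.abs(np.fft.fft(x)) ** 2
    G = np.ones(n)  # cascade of low-pass responses
    energies = []
    for j in range(levels):
        wj = w / alpha**j
        h0, h1 = _tqwt_channel_responses(wj, alpha, beta)
        energies.append(float(np.sum(X2 * (G * h1) ** 2) / n))
        G = G * h0
    energies.append(float(np.sum(X2 * G**2) / n))
    return np.array(energies)


def tqwt_features(x: np.ndarray, prefix: str = "") -> dict[str, float]:
    e = tqwt_band_energies(x)
    total = float(np.sum(e))
    p = e / total if total > 0 else np.full_like(e, 1.0 / e.size)
    out = {f"{prefix}tqwt_band{j}_frac": float(p[j]) for j in range(p.size)}
    out[prefix + "tqwt_entropy"] = float(-np.sum(p[p > 0] * np.log(p[p > 0]))
                                         / np.log(max(p.size, 2)))
    return out


# ---------------------------------------------------------------------------
# harmonic-percussive source separation
# ---------------------------------------------------------------------------


def hpss_energy_ratio(x: np.ndarray, fs: float, nperseg: int = 512,
                      kernel: int = 17) -> float:
    """Harmonic/percussive energy ratio from median-filtered STFT magnitude."""
    _, _, Z = sps.stft(np.asarray(x, dtype=float), fs=fs, nperseg=nperseg)
    S = np.abs(Z)
    harm = ndimage.median_filter(S, size=(1, kernel))
    perc = ndimage.median_filter(S, size=(kernel, 1))
    eh = float(np.sum(harm**2))
    ep = float(np.sum(perc**2))
    return eh / max(ep, 1e-300)


def timefreq_features(x: np.ndarray, fs: float, n_mfcc: int = 13,
                      prefix: str = "") -> dict[str, float]:
    """Bundle of all time-frequency features for one phase."""
    out: dict[str, float] = {}
    out.update(mfcc_features(x, fs, n_mfcc, prefix))
    out.update(wavelet_features(x, fs, prefix=prefix))
    out.update(cqt_features(x, fs, prefix))
    out.update(tqwt_features(x, prefix))
    out[prefix + "hpss_ratio"] = hpss_energy_ratio(x, fs)
    return out
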