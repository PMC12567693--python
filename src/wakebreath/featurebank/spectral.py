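"""Spectral-shape features computed from a PSD, optionally band-restricted."""

from __future__ import annotations

import numpy as np
from scipy import stats


def spectral_features(freqs: np.ndarray, psd: np.ndarray,
                      band: tuple[float, float] | None = None,
                      prefix: str = "") -> dict[str, float]:
    """Shape statistics of a PSD within ``band`` (or the full grid).

    Entropy is the Shannon entropy of the normalized PSD treated as a
    distribution over bins, normalized by log(K) to [0, 1]; crest is
    max/mean power; centroid/bandwidth are the power-weighted mean/SD of
    frequency; skewness/kurtosis are the corresponding weighted moments;
    flux is the RMS of the first difference of the normalized PSD (spectral
    roughness of a single estimate).
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if band is not None:
        sel = (freqs >= band[0]) & (freqs < band[1])
        freqs, psd = freqs[sel], psd[sel]
    names = ["mean_power", "centroid", "bandwidth", "entropy", "crest", "skewness",
             "kurtosis", "flux", "peak_frequency", "median_power", "max_power", "sd_power"]
    if psd.size == 0 or np.sum(psd) <= 0:
        return {prefix + n: float("nan") for n in names}
    p = psd / np.sum(psd)
    centroid = float(np.sum(p * freqs))
    bandwidth = float(np.sqrt(np.sum(p * (freqs - centroid) ** 2)))
    k = psd.size
    entropy = 0.0 if k == 1 else float(-np.sum(p[p > 0] * np.log(p[p > 0])) / np.log(k))
    mean_power = float(np.mean(psd))
    out = {
        "mean_power": mean_power,
        "centroid": centroid,
        "bandwidth": bandwidth,
        "entropy": entropy,
        "crest": float(np.max(psd) / mean_power),
        "skewness": _weighted_skew(freqs, p, centroid, bandwidth),
        "kurtosis": _weighted_kurt(freqs, p, centroid, bandwidth),
        "flux": float(np.sqrt(np.mean(np.diff(p) ** 2))) if k > 1 else 0.0,
        "peak_frequency": float(freqs[np.argmax(psd)]),
        "median_power": float(np.median(psd)),
        "max_power": float(np.max(psd)),
        "sd_power": float(np.std(psd)),
    }
    return {prefix + n: v for n, v in out.items()}


def _weighted_skew(f: np.ndarray, p: np.ndarray, mu: float, sd: float) -> float:
    if sd == 0:
        return 0.0
    return float(np.sum(p * ((f - mu) / sd) ** 3))


def _weighted_kurt(f: np.ndarray, p: np.ndarray, mu: float, sd: float) -> float:
    if sd == 0:
        return 0.0
    return float(np.sum(p * ((f - mu) / sd) ** 4))


def amplitude_distribution_features(x: np.ndarray, prefix: str = "") -> dict[str, float]:
    """CDF-based amplitude metrics (quantiles, IQR, sample skew/kurtosis)."""
    x = np.asarray(x, dtype=float)
    q = np.quantile(x, [0.1, 0.25, 0.5, 0.75, 0.9])
    return {
        prefix + "q10": float(q[0]), prefix + "q25": float(q[1]),
        prefix + "median": float(q[2]), prefix + "q75": float(q[3]),
        prefix + "q90": float(q[4]), prefix + "iqr": float(q[3] - q[1]),
        prefix + "amp_skew": float(stats.skew(x)),
        prefix + "amp_kurt": float(stats.kurtosis(x)),
    }
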