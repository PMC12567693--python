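"""Welch PSD, bispectrum estimation, confidence bands and gap detection.

The statistical core of the pipeline: per-frequency-bin normal-range bands of
the form mu(f) +/- 1.96 sigma(f) over a reference group of spectra, their
bootstrap analogue for bispectrum magnitude/phase maps (which avoids the
Gaussianity assumption), and the detection of "gaps" — frequency intervals or
bispectral regions where a target estimate escapes the band. Band parameters
are fitted on training subjects only and frozen for application to test data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import signal as sps

Z_95 = 1.96  # normal 95% multiplier used by the parametric band


@dataclass(frozen=True)
class WelchParams:
    nperseg: int = 1024
    overlap: float = 0.5
    window: str = "hann"
    detrend: str | bool = "constant"


@dataclass
class SpectralEstimate:
    freqs: np.ndarray
    psd: np.ndarray
    params: WelchParams = field(default_factory=WelchParams)


@dataclass
class CIBand:
    """Per-bin normal-range band: bounds = mu(f) +/- z sigma(f)."""

    freqs: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    z: float = Z_95
    n_group: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(getattr(self, k)).tolist()
                   for k in ("freqs", "mu", "sigma", "lower", "upper")}
        payload["z"] = self.z
        payload["n_group"] = self.n_group
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CIBand":
        d = json.loads(Path(path).read_text())
        return cls(*(np.asarray(d[k]) for k in ("freqs", "mu", "sigma", "lower", "upper")),
                   z=d["z"], n_group=d["n_group"])


@dataclass
class BispectrumEstimate:
    f1: np.ndarray
    f2: np.ndarray
    magnitude: np.ndarray  # |B| on the (f1, f2) grid
    phase: np.ndarray
    bicoherence: np.ndarray  # in [0, 1]
    n_segments: int = 0


@dataclass
class GapSet:
    """Detected out-of-band intervals (PSD) and boxes (bispectrum)."""

    #: (start_bin, end_bin, f_start, f_end, direction) with half-open bins
    psd_gaps: list[tuple[int, int, float, float, str]] = field(default_factory=list)
    #: (r0, r1, c0, c1, direction): half-open bin box rows (f2) x cols (f1)
    bispec_regions: list[tuple[int, int, int, int, str]] = field(default_factory=list)


def welch_psd(x: np.ndarray, fs: float, params: WelchParams = WelchParams()) -> SpectralEstimate:
    """Welch averaged-modified-periodogram PSD (density scaling)."""
    x = np.asarray(x, dtype=float)
    if x.size < params.nperseg:
        raise ValueError(f"signal shorter than one window ({x.size} < {params.nperseg})")
    noverlap = int(params.nperseg * params.overlap)
    f, pxx = sps.welch(x, fs=fs, window=params.window, nperseg=params.nperseg,
                       noverlap=noverlap, detrend=params.detrend, scaling="density")
    return SpectralEstimate(freqs=f, psd=pxx, params=params)


def build_ci_band(group: Sequence[SpectralEstimate] | np.ndarray, z: float = Z_95) -> CIBand:
    """Per-bin mean/SD band over a reference group of spectra.

    Accepts either SpectralEstimates on a shared grid or a raw
    (n_group, n_bins) array (freqs default to bin indices).
    """
    if isinstance(group, np.ndarray):
        mat = np.asarray(group, dtype=float)
        freqs = np.arange(mat.shape[1], dtype=float)
    else:
        if len(group) < 2:
            raise ValueError("need at least 2 spectra")
        freqs = group[0].freqs
        for g in group[1:]:
            if g.freqs.shape != freqs.shape or not np.allclose(g.freqs, freqs):
                raise ValueError("spectra are on mismatched frequency grids")
        mat = np.vstack([g.psd for g in group])
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    mu = mat.mean(axis=0)
    sigma = mat.std(axis=0, ddof=1)
    return CIBand(freqs=freqs, mu=mu, sigma=sigma,
                  lower=mu - z * sigma, upper=mu + z * sigma, z=z, n_group=mat.shape[0])


def _runs(mask: np.ndarray) -> np.ndarray:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return edges.reshape(-1, 2)


def detect_psd_gaps(target: SpectralEstimate | np.ndarray, band: CIBand,
                    min_width_bins: int = 3) -> GapSet:
    """Mark contiguous runs of bins where the target escapes the band.

    Runs shorter than ``min_width_bins`` are discarded; each surviving
    interval is labelled 'above' or 'below'.
    """
    psd = target.psd if isinstance(target, SpectralEstimate) else np.asarray(target, dtype=float)
    if psd.shape != band.mu.shape:
        raise ValueError("target grid does not match band grid")
    gaps: list[tuple[int, int, float, float, str]] = []
    for mask, direction in ((psd > band.upper, "above"), (psd < band.lower, "below")):
        for s, e in _runs(mask):
            if e - s >= min_width_bins:
                gaps.append((int(s), int(e), float(band.freqs[s]),
                             float(band.freqs[min(e, len(band.freqs) - 1)]), direction))
    gaps.sort()
    return GapSet(psd_gaps=gaps)


def estimate_bispectrum(x: np.ndarray, fs: float, nfft: int = 256,
                        overlap: float = 0.5, window: str = "hann") -> BispectrumEstimate:
    """Direct (FFT segment-averaged) bispectrum on a square principal-domain grid.

    B(f1, f2) = E[X(f1) X(f2) X*(f1 + f2)] over Hann-windowed segments; the
    grid is restricted to f1, f2 in [0, fs/4] so f1 + f2 stays below Nyquist
    and B(f1, f2) = B(f2, f1) holds on the full grid. Bicoherence uses the
    normalization b^2 = |E[X1 X2 X3*]|^2 / (E[|X1 X2|^2] E[|X3|^2]), which is
    bounded in [0, 1] by Cauchy-Schwarz.
    """
    x = np.asarray(x, dtype=float)
    step = max(int(nfft * (1 - overlap)), 1)
    n_seg = (x.size - nfft) // step + 1 if x.size >= nfft else 0
    if n_seg < 4:
        raise ValueError("fewer than 4 segments: bispectrum variance too high")
    win = sps.get_window(window, nfft)
    m = nfft // 4
    acc = np.zeros((m + 1, m + 1), dtype=complex)
    p12 = np.zeros((m + 1, m + 1))
    p3 = np.zeros((m + 1, m + 1))
    idx = np.arange(m + 1)
    sum_idx = idx[:, None] + idx[None, :]
    for s in range(n_seg):
        seg = x[s * step: s * step + nfft] * win
        X = np.fft.rfft(seg - seg.mean())
        x1x2 = X[idx][:, None] * X[idx][None, :]
        x3 = X[sum_idx]
        acc += x1x2 * np.conj(x3)
        p12 += np.abs(x1x2) ** 2
        p3 += np.abs(x3) ** 2
    B = acc / n_seg
    denom = np.sqrt((p12 / n_seg) * (p3 / n_seg))
    bicoh = np.abs(B) / np.maximum(denom, 1e-300)
    freqs = idx * fs / nfft
    return BispectrumEstimate(f1=freqs, f2=freqs, magnitude=np.abs(B),
                              phase=np.angle(B), bicoherence=np.clip(bicoh, 0, 1),
                              n_segments=n_seg)


def _weighted_quantile(sorted_vals: np.ndarray, w_sorted: np.ndarray,
                       p: float) -> np.ndarray:
    """Weighted quantile along axis 0 with median-unbiased plotting positions.

    Positions generalize the (k - 1/3)/(n + 1/3) convention to weights
    normalized to mean 1; at uniform weights this is the standard
    median-unbiased empirical quantile.
    """
    c = np.cumsum(w_sorted, axis=0)
    total = c[-1]
    pos = (c - w_sorted / 3.0) / (total + 1.0 / 3.0)
    idx = np.sum(pos < p, axis=0)  # first position >= p per bin
    n = sorted_vals.shape[0]
    flat_vals = sorted_vals.reshape(n, -1)
    flat_pos = pos.reshape(n, -1)
    cols = np.arange(flat_vals.shape[1])
    hi = np.clip(idx.reshape(-1), 0, n - 1)
    lo = np.clip(hi - 1, 0, n - 1)
    p_lo, p_hi = flat_pos[lo, cols], flat_pos[hi, cols]
    v_lo, v_hi = flat_vals[lo, cols], flat_vals[hi, cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(p_hi > p_lo, (p - p_lo) / (p_hi - p_lo), 0.0)
    t = np.clip(t, 0.0, 1.0)
    out = v_lo + t * (v_hi - v_lo)
    return out.reshape(sorted_vals.shape[1:])


def bootstrap_bounds(values: np.ndarray, n_boot: int = 500, alpha: float = 0.05,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level bootstrap normal-range bounds, per bin.

    ``values`` is (n_subjects, ...). The ``n_boot`` with-replacement
    subject resamples are pooled — equivalent to one multinomial weight
    draw of ``n * n_boot`` over subjects — and the per-bin empirical
    alpha/2 and 1-alpha/2 quantiles of the pooled member distribution are
    returned (median-unbiased positions, so a fresh member map is covered
    at approximately the nominal level with no Gaussianity assumption).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = rng or np.random.default_rng()
    # pooled bootstrap: total per-subject draw counts across all resamples
    weights = rng.multinomial(n * n_boot, np.full(n, 1.0 / n)) / float(n_boot)
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    w_sorted = weights[order]
    lo = _weighted_quantile(sorted_vals, w_sorted, alpha / 2)
    hi = _weighted_quantile(sorted_vals, w_sorted, 1 - alpha / 2)
    return lo, hi


def bootstrap_bispec_bounds(group: Sequence[BispectrumEstimate], n_boot: int = 500,
                            alpha: float = 0.05, rng: np.random.Generator | None = None,
                            ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Bootstrap bounds for magnitude and phase of a group of bispectra."""
    mags = np.stack([b.magnitude for b in group])
    phases = np.stack([b.phase for b in group])
    rng = rng or np.random.default_rng()
    return {
        "magnitude": bootstrap_bounds(mags, n_boot, alpha, rng),
        "phase": bootstrap_bounds(phases, n_boot, alpha, rng),
    }


def detect_bispec_gap_regions(target: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                              min_area_bins: int = 9) -> GapSet:
    """Out-of-bounds connected components (8-connectivity) -> bounding boxes."""
    target = np.asarray(target, dtype=float)
    structure = np.ones((3, 3), dtype=int)
    regions: list[tuple[int, int, int, int, str]] = []
    for mask, direction in ((target > upper, "above"), (target < lower, "below")):
        labels, n = ndimage.label(mask, structure=structure)
        for i, sl in enumerate(ndimage.find_objects(labels), start=1):
            if sl is None:
                continue
            area = int(np.sum(labels[sl] == i))
            if area >= min_area_bins:
                regions.append((sl[0].start, sl[0].stop, sl[1].start, sl[1].stop, direction))
    regions.sort()
    return GapSet(bispec_regions=regions)
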