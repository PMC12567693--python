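"""Nonlinear-dynamics descriptors: fractal dimensions, Hurst, Lyapunov,
entropies and recurrence quantification analysis (RQA).

All estimators follow the standard published algorithms (Katz, Higuchi,
detrended fluctuation analysis, Rosenstein largest Lyapunov exponent, sample
and approximate entropy, recurrence plots with fixed embedding). Long phases
are decimated/truncated to a capped length before the quadratic-cost
estimators; caps are configurable.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension; exactly 1 for a straight line."""
    x = np.asarray(x, dtype=float)
    n = x.size - 1
    if n < 1:
        return float("nan")
    dists = np.sqrt(1.0 + np.diff(x) ** 2)
    L = float(np.sum(dists))
    a = L / n
    d = float(np.max(np.sqrt(np.arange(x.size) ** 2 + (x - x[0]) ** 2)))
    if d <= 0 or a <= 0:
        return 1.0
    return float(np.log10(L / a) / np.log10(d / a)) if d != a else 1.0


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension (slope of log curve length vs log 1/k)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    lk = []
    ks = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            lm = np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / (k * (idx.size - 1))
            lengths.append(lm / k)
        if lengths:
            lk.append(np.log(np.mean(lengths)))
            ks.append(np.log(1.0 / k))
    slope = np.polyfit(ks, lk, 1)[0]
    return float(slope)


def hurst_dfa(x: np.ndarray, min_box: int = 8, n_scales: int = 10) -> float:
    """Hurst exponent via detrended fluctuation analysis (DFA-1 alpha)."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - np.mean(x))
    n = y.size
    scales = np.unique(np.floor(np.logspace(np.log10(min_box), np.log10(n // 4),
                                            n_scales)).astype(int))
    flucts = []
    for s in scales:
        n_seg = n // s
        if n_seg < 2:
            continue
        segs = y[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s)
        tm = t - t.mean()
        beta = segs @ tm / np.sum(tm**2)
        resid = segs - segs.mean(axis=1, keepdims=True) - np.outer(beta, tm)
        flucts.append(np.sqrt(np.mean(resid**2)))
    valid = [i for i, f in enumerate(flucts) if f > 0]
    slope = np.polyfit(np.log(scales[valid]), np.log(np.array(flucts)[valid]), 1)[0]
    return float(slope)


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = x.size - (dim - 1) * delay
    if n < 2:
        raise ValueError("signal too short for embedding")
    return np.column_stack([x[i * delay: i * delay + n] for i in range(dim)])


def first_autocorr_zero(x: np.ndarray) -> int:
    """Lag of the first zero crossing of the autocorrelation (>= 1)."""
    x = np.asarray(x, dtype=float) - np.mean(x)
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    z = np.flatnonzero(ac < 0)
    return int(z[0]) if z.size else 1


def largest_lyapunov(x: np.ndarray, dim: int = 3, delay: int | None = None,
                     fit_len: int = 20) -> float:
    """Rosenstein estimate of the largest Lyapunov exponent (per sample)."""
    x = np.asarray(x, dtype=float)
    delay = delay or max(first_autocorr_zero(x), 1)
    emb = _embed(x, dim, delay)
    n = emb.shape[0]
    mean_period = max(delay, 1)
    d = squareform(pdist(emb))
    for i in range(n):
        lo = max(i - mean_period, 0)
        hi = min(i + mean_period + 1, n)
        d[i, lo:hi] = np.inf
    nn = np.argmin(d, axis=1)
    steps = min(fit_len, n - 1)
    div = np.full(steps, np.nan)
    for k in range(1, steps + 1):
        valid = (np.arange(n) + k < n) & (nn + k < n)
        if not np.any(valid):
            break
        dk = np.linalg.norm(emb[np.arange(n)[valid] + k] - emb[nn[valid] + k], axis=1)
        dk = dk[dk > 0]
        if dk.size:
            div[k - 1] = np.mean(np.log(dk))
    t = np.flatnonzero(np.isfinite(div))
    if t.size < 2:
        return float("nan")
    return float(np.polyfit(t + 1, div[t], 1)[0])


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -log of conditional probability of template match growth."""
    x = np.asarray(x, dtype=float)
    r = r if r is not None else 0.2 * np.std(x)
    n = x.size

    def count(mm: int) -> int:
        emb = _embed(x, mm, 1)
        d = pdist(emb, metric="chebyshev")
        return int(np.sum(d <= r))

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) per Pincus (includes self-matches)."""
    x = np.asarray(x, dtype=float)
    r = r if r is not None else 0.2 * np.std(x)

    def phi(mm: int) -> float:
        emb = _embed(x, mm, 1)
        d = squareform(pdist(emb, metric="chebyshev"))
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def rqa_features(x: np.ndarray, dim: int = 3, delay: int | None = None,
                 radius_frac: float = 0.1, min_line: int = 2) -> dict[str, float]:
    """Recurrence rate, determinism and laminarity of the recurrence plot.

    Embedding: dimension ``dim``, delay = first autocorrelation zero;
    recurrence threshold = ``radius_frac`` of the maximum phase-space
    distance. Determinism/laminarity count recurrent points on diagonal/
    vertical lines of length >= ``min_line``.
    """
    x = np.asarray(x, dtype=float)
    delay = delay or max(first_autocorr_zero(x), 1)
    emb = _embed(x, dim, delay)
    d = squareform(pdist(emb))
    rp = d <= radius_frac * np.max(d)
    n = rp.shape[0]
    total = int(np.sum(rp))
    rr = total / float(n * n)

    def line_points(mat: np.ndarray, diagonals: bool) -> int:
        pts = 0
        if diagonals:
            for off in range(-(n - 1), n):
                line = np.diagonal(mat, offset=off)
                pts += _points_in_runs(line, min_line)
        else:
            for j in range(n):
                pts += _points_in_runs(mat[:, j], min_line)
        return pts

    det = line_points(rp, True) / max(total, 1)
    lam = line_points(rp, False) / max(total, 1)
    return {"recurrence_rate": rr, "determinism": float(det), "laminarity": float(lam)}


def _points_in_runs(line: np.ndarray, min_line: int) -> int:
    line = np.asarray(line, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], line.view(np.int8), [0]))))
    runs = edges.reshape(-1, 2)
    lens = runs[:, 1] - runs[:, 0]
    return int(np.sum(lens[lens >= min_line]))


def nonlinear_features(x: np.ndarray, fs: float, max_samples: int = 1500,
                       prefix: str = "") -> dict[str, float]:
    """Bundle of nonlinear descriptors; the signal is decimated to at most
    ``max_samples`` points before the quadratic-cost estimators."""
    x = np.asarray(x, dtype=float)
    step = max(x.size // max_samples, 1)
    xs = x[::step][:max_samples]
    out = {
        prefix + "katz_fd": katz_fd(xs),
        prefix + "higuchi_fd": higuchi_fd(xs),
        prefix + "hurst": hurst_dfa(xs),
        prefix + "lyapunov": largest_lyapunov(xs[:600]),
        prefix + "sampen": sample_entropy(xs[:800]),
        prefix + "apen": approximate_entropy(xs[:800]),
    }
    rqa = rqa_features(xs[:600])
    out.update({prefix + "rqa_" + k: v for k, v in rqa.items()})
    return out
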