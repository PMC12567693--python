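"""Texture and binary-morphology features of spectro-/bispectral images.

GLCM and LBP come from scikit-image; the probabilistic (soft) binary pattern
is a locally z-scored, sigmoid-weighted variant of LBP implemented here (the
literature gives no canonical formulation, see docs/methods.md). Morphology
operates on the image binarized at a configurable intensity quantile.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix, graycoprops, local_binary_pattern
from skimage.measure import euler_number, label, regionprops


def _quantize(img: np.ndarray, levels: int = 8) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = float(np.min(img)), float(np.max(img))
    if hi <= lo:
        return np.zeros_like(img, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm_features(img: np.ndarray, levels: int = 8, prefix: str = "") -> dict[str, float]:
    """GLCM contrast/correlation/homogeneity/energy, averaged over the
    (0,1) and (1,0) offsets on the 8-level quantized image."""
    q = _quantize(img, levels)
    glcm = graycomatrix(q, distances=[1], angles=[0, np.pi / 2], levels=levels,
                        symmetric=True, normed=True)
    out = {}
    for prop in ("contrast", "correlation", "homogeneity", "energy"):
        vals = graycoprops(glcm, prop)
        out[prefix + "glcm_" + prop] = float(np.mean(vals))
    return out


def lbp_features(img: np.ndarray, p: int = 8, r: float = 1.0,
                 prefix: str = "") -> dict[str, float]:
    """Histogram statistics of uniform LBP codes."""
    codes = local_binary_pattern(np.asarray(img, dtype=float), p, r, method="uniform")
    n_bins = p + 2
    hist, _ = np.histogram(codes, bins=np.arange(n_bins + 1), density=True)
    ent = float(-np.sum(hist[hist > 0] * np.log(hist[hist > 0])) / np.log(n_bins))
    return {
        prefix + "lbp_mean": float(np.mean(codes)),
        prefix + "lbp_sd": float(np.std(codes)),
        prefix + "lbp_entropy": ent,
        prefix + "lbp_uniform_frac": float(hist[:-1].sum()),
    }


def pbp_features(img: np.ndarray, tau: float = 0.5, window: int = 5,
                 prefix: str = "") -> dict[str, float]:
    """Soft (probabilistic) binary-pattern statistics.

    The image is locally z-scored over a ``window`` x ``window`` neighbourhood;
    each of the 8 neighbour comparisons of LBP is replaced by the sigmoid
    probability sigma((neighbour - center)/tau). Features summarize the mean
    bit-probability map (its mean, SD, and binary entropy).
    """
    img = np.asarray(img, dtype=float)
    mean = ndimage.uniform_filter(img, window)
    sq = ndimage.uniform_filter(img**2, window)
    sd = np.sqrt(np.maximum(sq - mean**2, 1e-12))
    z = (img - mean) / sd
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    probs = np.zeros_like(z)
    for dy, dx in shifts:
        nb = np.roll(np.roll(z, dy, axis=0), dx, axis=1)
        probs += 1.0 / (1.0 + np.exp(-(nb - z) / tau))
    probs /= len(shifts)
    pclip = np.clip(probs, 1e-9, 1 - 1e-9)
    bit_ent = float(np.mean(-pclip * np.log2(pclip) - (1 - pclip) * np.log2(1 - pclip)))
    return {
        prefix + "pbp_mean": float(np.mean(probs)),
        prefix + "pbp_sd": float(np.std(probs)),
        prefix + "pbp_entropy": bit_ent,
    }


def morphology_features(img: np.ndarray, threshold_quantile: float = 0.75,
                        prefix: str = "") -> dict[str, float]:
    """Binary morphology of the image thresholded at an intensity quantile.

    Components are 8-connected and holes 4-connected, so
    euler = components - holes.
    """
    img = np.asarray(img, dtype=float)
    binary = img > np.quantile(img, threshold_quantile)
    lbl = label(binary, connectivity=2)
    n_components = int(lbl.max())
    euler = int(euler_number(binary, connectivity=2)) if binary.any() else 0
    n_holes = n_components - euler
    bbox_area = 0.0
    if n_components:
        rows = np.any(binary, axis=1)
        cols = np.any(binary, axis=0)
        r0, r1 = np.flatnonzero(rows)[[0, -1]]
        c0, c1 = np.flatnonzero(cols)[[0, -1]]
        bbox_area = float((r1 - r0 + 1) * (c1 - c0 + 1))
    areas = [p.area for p in regionprops(lbl)] if n_components else []
    return {
        prefix + "n_components": float(n_components),
        prefix + "n_holes": float(n_holes),
        prefix + "euler_number": float(euler),
        prefix + "bounding_box_area": bbox_area,
        prefix + "fg_fraction": float(np.mean(binary)),
        prefix + "mean_component_area": float(np.mean(areas)) if areas else 0.0,
    }


def image_features(img: np.ndarray, prefix: str = "") -> dict[str, float]:
    """All texture + morphology features of one matrix image."""
    out: dict[str, float] = {}
    out.update(glcm_features(img, prefix=prefix))
    out.update(lbp_features(img, prefix=prefix))
    out.update(pbp_features(img, prefix=prefix))
    out.update(morphology_features(img, prefix=prefix))
    return out
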