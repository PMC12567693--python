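"""Bispectral features over statistically significant (gap) regions."""

from __future__ import annotations

import numpy as np

from wakebreath.spectra import BispectrumEstimate, GapSet


def bispectral_features(bispec: BispectrumEstimate, gaps: GapSet | None = None,
                        prefix: str = "") -> dict[str, float]:
    """Magnitude/bicoherence statistics, entropy, symmetry, and box geometry.

    Magnitude statistics are computed over the union of gap-region bins when a
    region list is supplied (the statistically significant regions), else over
    the whole principal-domain grid. Box geometry (area, perimeter, aspect
    ratio in Hz) comes from the gap bounding boxes; with no regions the
    geometry features are 0 and the magnitude statistics are missing-masked.
    """
    mag = bispec.magnitude
    regions = list(gaps.bispec_regions) if gaps is not None else []
    df1 = float(bispec.f1[1] - bispec.f1[0]) if len(bispec.f1) > 1 else 1.0
    df2 = float(bispec.f2[1] - bispec.f2[0]) if len(bispec.f2) > 1 else 1.0

    out: dict[str, float] = {}
    if gaps is None:
        sel = np.ones_like(mag, dtype=bool)
    else:
        sel = np.zeros_like(mag, dtype=bool)
        for r0, r1, c0, c1, _ in regions:
            sel[r0:r1, c0:c1] = True
    stat_names = ["mag_mean", "mag_max", "mag_sd", "total_energy", "bispec_entropy",
                  "bicoh_mean", "bicoh_max"]
    if not np.any(sel):
        out.update({prefix + n: float("nan") for n in stat_names})
    else:
        m = mag[sel]
        e = m**2
        p = e / np.sum(e) if np.sum(e) > 0 else np.full_like(e, 1.0 / e.size)
        ent = 0.0 if e.size == 1 else float(-np.sum(p[p > 0] * np.log(p[p > 0])) / np.log(e.size))
        out.update({
            prefix + "mag_mean": float(np.mean(m)),
            prefix + "mag_max": float(np.max(m)),
            prefix + "mag_sd": float(np.std(m)),
            prefix + "total_energy": float(np.sum(e)),
            prefix + "bispec_entropy": ent,
            prefix + "bicoh_mean": float(np.mean(bispec.bicoherence[sel])),
            prefix + "bicoh_max": float(np.max(bispec.bicoherence[sel])),
        })
    # symmetry of the full map: relative antisymmetric energy (0 for B = B^T)
    asym = mag - mag.T
    sym = mag + mag.T
    out[prefix + "asymmetry"] = float(np.linalg.norm(asym) / max(np.linalg.norm(sym), 1e-300))

    areas, perims, aspects = [], [], []
    for r0, r1, c0, c1, _ in regions:
        h, w = (r1 - r0) * df2, (c1 - c0) * df1
        areas.append(h * w)
        perims.append(2 * (h + w))
        aspects.append(max(h, w) / max(min(h, w), 1e-300))
    out[prefix + "n_regions"] = float(len(regions))
    out[prefix + "box_area"] = float(np.sum(areas)) if areas else 0.0
    out[prefix + "box_perimeter"] = float(np.sum(perims)) if perims else 0.0
    out[prefix + "box_aspect_ratio"] = float(np.mean(aspects)) if aspects else 0.0
    return out


def region_energy(mag: np.ndarray, box: tuple[int, int, int, int]) -> float:
    """Total |B|^2 energy inside one half-open bin box (r0, r1, c0, c1)."""
    r0, r1, c0, c1 = box
    return float(np.sum(np.asarray(mag)[r0:r1, c0:c1] ** 2))
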