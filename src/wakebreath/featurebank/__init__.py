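"""Multi-domain acoustic feature bank: per-phase extraction and per-subject
aggregation into a subjects x features table.

Feature families (each toggleable in :class:`FeatureConfig`):

* ``spectral``   — PSD shape statistics, full-band and per detected gap band
* ``bispectral`` — bispectrum magnitude/bicoherence statistics and gap-region
  box geometry
* ``time``       — amplitude/regularity descriptors
* ``timefreq``   — MFCC, wavelet, CQT, TQWT, HPSS
* ``nonlinear``  — fractal dimensions, Hurst, Lyapunov, entropies, RQA
* ``image``      — texture/morphology of the spectrogram (and bispectrum) image

Per-subject aggregation is the mean over that subject's kept phases of each
(route, phase_type) stream; missing streams are NaN-masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from wakebreath.featurebank.bispectral import bispectral_features, region_energy  # noqa: F401
from wakebreath.featurebank.imagefeat import image_features  # noqa: F401
from wakebreath.featurebank.nonlinear import nonlinear_features  # noqa: F401
from wakebreath.featurebank.spectral import (  # noqa: F401
    amplitude_distribution_features,
    spectral_features,
)
from wakebreath.featurebank.timedomain import time_features  # noqa: F401
from wakebreath.featurebank.timefreq import timefreq_features  # noqa: F401
from wakebreath.preprocess import BreathPhase
from wakebreath.spectra import GapSet, WelchParams, estimate_bispectrum, welch_psd

ALL_FAMILIES = ("spectral", "bispectral", "time", "timefreq", "nonlinear", "image")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    domain: str  # one of ALL_FAMILIES
    route: str
    phase_type: str
    gap_band: tuple[float, float] | None = None


@dataclass(frozen=True)
class FeatureConfig:
    families: tuple[str, ...] = ("spectral", "time", "timefreq")
    welch: WelchParams = field(default_factory=WelchParams)
    #: per-experiment gap bands (Hz) for band-restricted spectral features
    gap_bands: tuple[tuple[float, float], ...] = ()
    bispec_nfft: int = 256
    n_mfcc: int = 13
    nonlinear_max_samples: int = 1500

    def validate(self) -> None:
        for fam in self.families:
            if fam not in ALL_FAMILIES:
                raise ValueError(f"unknown feature family {fam!r}")


@dataclass
class FeatureTable:
    """Subjects x named features with a missing mask (NaN-backed)."""

    frame: pd.DataFrame
    descriptors: list[FeatureDescriptor] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="subject_id")

    def to_json_sidecar(self, path) -> None:
        import dataclasses
        import json

        payload = [dataclasses.asdict(d) for d in self.descriptors]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def phase_features(phase: BreathPhase, config: FeatureConfig = FeatureConfig()
                   ) -> dict[str, float]:
    """All configured features of one breath phase (unprefixed names)."""
    config.validate()
    x, fs = np.asarray(phase.samples, dtype=float), phase.fs
    out: dict[str, float] = {}
    if "spectral" in config.families:
        est = welch_psd(x, fs, config.welch)
        out.update(spectral_features(est.freqs, est.psd, prefix="sp_"))
        out.update(amplitude_distribution_features(x, prefix="sp_"))
        for i, band in enumerate(config.gap_bands):
            out.update(spectral_features(est.freqs, est.psd, band=band,
                                         prefix=f"gap{i}_"))
    if "bispectral" in config.families:
        try:
            bis = estimate_bispectrum(x, fs, nfft=config.bispec_nfft)
            out.update(bispectral_features(bis, None, prefix="bis_"))
        except ValueError:
            pass
    if "time" in config.families:
        out.update(time_features(x, fs, prefix="td_"))
    if "timefreq" in config.families:
        out.update(timefreq_features(x, fs, config.n_mfcc, prefix="tf_"))
    if "nonlinear" in config.families:
        out.update(nonlinear_features(x, fs, config.nonlinear_max_samples, prefix="nl_"))
    if "image" in config.families:
        _, _, Z = sps.stft(x, fs=fs, nperseg=256)
        out.update(image_features(np.log(np.abs(Z) + 1e-12), prefix="img_"))
    return out


def assemble_feature_table(
    phases_by_subject: dict[str, list[BreathPhase]],
    config: FeatureConfig = FeatureConfig(),
) -> FeatureTable:
    """Aggregate per-phase features to one row per subject.

    Each (route, phase_type) stream is averaged over the subject's kept
    phases and prefixed ``{route}_{insp|exp}_``; subjects missing a stream
    get NaN there. Column order is deterministic. A subject with zero kept
    phases yields an all-NaN row (with a warning).
    """
    import warnings

    rows: dict[str, dict[str, float]] = {}
    all_cols: list[str] = []
    seen = set()
    for sid, phases in phases_by_subject.items():
        acc: dict[str, list[float]] = {}
        kept = [p for p in phases if p.kept]
        if not kept:
            warnings.warn(f"subject {sid} has no kept phases; row is all-missing")
        for p in kept:
            stream = f"{p.route}_{'insp' if p.phase_type == 'inspiration' else 'exp'}_"
            for name, val in phase_features(p, config).items():
                col = stream + name
                acc.setdefault(col, []).append(val)
                if col not in seen:
                    seen.add(col)
                    all_cols.append(col)
        rows[sid] = {c: float(np.nanmean(v)) if len(v) else float("nan")
                     for c, v in acc.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame.reindex(columns=sorted(all_cols), index=list(phases_by_subject))
    return FeatureTable(frame=frame,
                        descriptors=[_describe(c) for c in frame.columns])


_DOMAIN_PREFIX = {"sp": "spectral", "gap": "spectral", "bis": "bispectral",
                  "td": "time", "tf": "timefreq", "nl": "nonlinear",
                  "img": "image"}


def _describe(column: str) -> FeatureDescriptor:
    """Parse `{route}_{insp|exp}_{prefix}_{name}` into provenance fields."""
    route, phase, rest = column.split("_", 2)
    tag = rest.split("_", 1)[0].rstrip("0123456789")
    return FeatureDescriptor(
        name=column,
        domain=_DOMAIN_PREFIX.get(tag, "spectral"),
        route=route,
        phase_type="inspiration" if phase == "insp" else "expiration")
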