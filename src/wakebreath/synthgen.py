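"""Seeded synthetic tracheal breathing sound (TBS) and cohort generation.

The study data this pipeline targets are private, so every downstream stage is
exercised on synthetic material with *planted*, configurable severity-dependent
structure:

* an anthropometric cohort whose per-class distributions follow the published
  summary statistics of the four AHI severity groups (Non-OSA, Mild, Moderate,
  Severe), and
* per-subject audio recordings emulating the recording protocol — five cycles of
  deep breathing through the nose plus five through the mouth, sampled at
  10,240 Hz — in which each severity class receives a configurable spectral
  tilt and turbulence-band energy gain.

The acoustic effects are stand-ins chosen so planted differences are detectable
by the pipeline; they are not estimates of real airway acoustics.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile

SEVERITY_CLASSES = ("NonOSA", "Mild", "Moderate", "Severe")

#: AHI intervals (events/hour) defining each severity class, half-open.
AHI_BOUNDS = {
    "NonOSA": (0.0, 5.0),
    "Mild": (5.0, 15.0),
    "Moderate": (15.0, 30.0),
    "Severe": (30.0, 120.0),  # upper tail capped
}

DEFAULT_FS = 10240

ANTHRO_FIELDS = ("age", "sex", "bmi", "mps", "nc", "smoke")


@dataclass(frozen=True)
class ClassParams:
    """Per-severity-class anthropometric sampling parameters."""

    ahi_mean: float
    ahi_sd: float
    age_mean: float
    age_sd: float
    male_prob: float
    bmi_mean: float
    bmi_sd: float
    mps_probs: tuple[float, float, float, float]
    nc_mean: float
    nc_sd: float
    smoke_prob: float = 0.2


def _mps(counts: Sequence[float]) -> tuple[float, float, float, float]:
    total = float(sum(counts))
    return tuple(c / total for c in counts)  # type: ignore[return-value]


#: Published cohort summary statistics (mean ± SD, sex and Mallampati counts)
#: for the 199-subject study population, used as generator defaults.
DEFAULT_CLASS_PARAMS: dict[str, ClassParams] = {
    "NonOSA": ClassParams(1.2, 1.3, 46.8, 12.9, 29 / 74, 30.6, 6.2, _mps((41, 19, 6, 8)), 38.8, 4.0),
    "Mild": ClassParams(8.7, 2.6, 52.3, 11.6, 21 / 35, 34.3, 8.4, _mps((18, 6, 9, 1)), 42.1, 6.5),
    "Moderate": ClassParams(21.5, 4.2, 54.7, 11.3, 36 / 50, 33.8, 6.4, _mps((17, 17, 8, 8)), 43.1, 3.4),
    "Severe": ClassParams(69.5, 33.3, 48.9, 11.1, 30 / 40, 39.7, 8.7, _mps((5, 13, 14, 8)), 45.3, 3.6),
}

#: Published per-class subject counts.
DEFAULT_N_PER_CLASS = {"NonOSA": 74, "Mild": 35, "Moderate": 50, "Severe": 40}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort draw."""

    n_per_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CLASS))
    class_params: dict[str, ClassParams] = field(default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in self.n_per_class:
            if name not in SEVERITY_CLASSES:
                raise ValueError(f"unknown severity class {name!r}")
            if self.n_per_class[name] < 1:
                raise ValueError(f"n_per_class[{name!r}] must be >= 1")
            if name not in self.class_params:
                raise ValueError(f"missing class_params for {name!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for name, p in self.class_params.items():
            if min(p.ahi_sd, p.age_sd, p.bmi_sd, p.nc_sd) < 0:
                raise ValueError(f"negative SD in class_params[{name!r}]")


@dataclass
class SubjectRecord:
    """One subject; any anthropometric field may be None (missing)."""

    subject_id: str
    ahi: float
    severity_class: str
    age: float | None
    sex: str | None  # "M"/"F"
    bmi: float | None
    mps: int | None  # Mallampati 1..4
    nc: float | None  # neck circumference, cm
    smoke: str | None  # "yes"/"no"


@dataclass(frozen=True)
class AcousticEffectSpec:
    """Planted per-class acoustic structure for one severity class.

    ``turb_gain_db`` raises the energy of the turbulence band ``turb_band``
    (Hz); ``tilt_db_per_octave`` sets the broadband spectral slope. The
    coupled-triad flag injects three sinusoids at (f1, f2, f1+f2) with phases
    summing (quadratic phase coupling) so bispectrum estimators have a known
    positive control.
    """

    tilt_db_per_octave: float = -6.0
    turb_band: tuple[float, float] = (800.0, 1600.0)
    turb_gain_db: float = 0.0
    #: per-subject SDs: subjects draw their own tilt/gain around the class
    #: mean, so classes overlap like real heterogeneous cohorts do
    tilt_sd_db_per_octave: float = 1.2
    turb_gain_sd_db: float = 3.5
    breath_rate_cpm: float = 10.0
    am_depth: float = 0.1
    snr_db: float = 25.0
    coupled_triad: bool = False
    triad_freqs: tuple[float, float] = (400.0, 520.0)
    triad_amp: float = 0.3

    def validate(self, fs: float) -> None:
        lo, hi = self.turb_band
        if not (0 < lo < hi <= fs / 2):
            raise ValueError("turbulence band must satisfy 0 < f_lo < f_hi <= fs/2")
        if not np.isfinite(self.snr_db):
            raise ValueError("SNR must be finite")
        if self.breath_rate_cpm <= 0:
            raise ValueError("breath rate must be positive")


#: Default planted effects: turbulence-band gain non-decreasing with severity,
#: calibrated so Non-OSA vs Severe is well separated while Non-OSA vs Mild is
#: hard (small gain step), mirroring the qualitative difficulty ordering.
DEFAULT_EFFECTS: dict[str, AcousticEffectSpec] = {
    "NonOSA": AcousticEffectSpec(tilt_db_per_octave=-7.0, turb_gain_db=0.0),
    "Mild": AcousticEffectSpec(tilt_db_per_octave=-6.7, turb_gain_db=1.0),
    "Moderate": AcousticEffectSpec(tilt_db_per_octave=-6.2, turb_gain_db=4.0),
    "Severe": AcousticEffectSpec(tilt_db_per_octave=-5.5, turb_gain_db=9.0),
}


@dataclass(frozen=True)
class PhaseAnnotation:
    """Ground-truth location of one breath phase, 0-based half-open samples."""

    phase_index: int
    phase_type: str  # "inspiration" | "expiration"
    start_sample: int
    end_sample: int


def _truncated_ahi(rng: np.random.Generator, p: ClassParams, bounds: tuple[float, float]) -> float:
    """Draw AHI from a log-normal moment-matched to (mean, sd), truncated to the class interval."""
    lo, hi = bounds
    mean, sd = max(p.ahi_mean, 1e-3), max(p.ahi_sd, 1e-6)
    # method of moments for log-normal
    s2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    for _ in range(200):
        x = float(rng.lognormal(mu, np.sqrt(s2)))
        if lo <= x < hi:
            return x
    return float(np.clip(rng.uniform(lo, hi), lo, hi - 1e-6))


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort of :class:`SubjectRecord` per the spec.

    Continuous fields are Gaussian with the class means/SDs, AHI is a
    truncated log-normal inside the class's AHI interval, and missing cells
    are injected completely at random at ``missing_rate`` over the
    anthropometric fields (never subject_id, severity or AHI).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    idx = 0
    for cls in SEVERITY_CLASSES:
        if cls not in spec.n_per_class:
            continue
        p = spec.class_params[cls]
        for _ in range(spec.n_per_class[cls]):
            rec = SubjectRecord(
                subject_id=f"S{idx:05d}",
                ahi=_truncated_ahi(rng, p, AHI_BOUNDS[cls]),
                severity_class=cls,
                age=float(rng.normal(p.age_mean, p.age_sd)),
                sex="M" if rng.random() < p.male_prob else "F",
                bmi=float(rng.normal(p.bmi_mean, p.bmi_sd)),
                mps=int(rng.choice(4, p=np.asarray(p.mps_probs) / sum(p.mps_probs)) + 1),
                nc=float(rng.normal(p.nc_mean, p.nc_sd)),
                smoke="yes" if rng.random() < p.smoke_prob else "no",
            )
            records.append(rec)
            idx += 1
    if spec.missing_rate > 0:
        for rec in records:
            for f in ANTHRO_FIELDS:
                if rng.random() < spec.missing_rate:
                    setattr(rec, f, None)
    return records


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, effects: AcousticEffectSpec,
                  band: tuple[float, float] = (75.0, 2800.0), f_ref: float = 300.0) -> np.ndarray:
    """Band-limited Gaussian noise with spectral tilt and turbulence-band gain."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    inband = (f >= band[0]) & (f <= band[1])
    with np.errstate(divide="ignore"):
        octaves = np.log2(np.maximum(f, 1e-9) / f_ref)
    amp[inband] = 10.0 ** (effects.tilt_db_per_octave * octaves[inband] / 20.0)
    lo, hi = effects.turb_band
    turb = inband & (f >= lo) & (f <= hi)
    amp[turb] *= 10.0 ** (effects.turb_gain_db / 20.0)
    x = np.fft.irfft(spec * amp, n=n)
    return x / (np.std(x) + 1e-30)


def _background_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Gentle 1/f-shaped Gaussian background, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec * shape, n=n)
    return x / (np.std(x) + 1e-30)


def synthesize_recording(
    subject: SubjectRecord,
    effects: AcousticEffectSpec,
    fs: float = DEFAULT_FS,
    route: str = "nose",
    n_cycles: int = 5,
    seed: int | None = None,
    noise: bool = True,
) -> tuple[np.ndarray, list[PhaseAnnotation]]:
    """Synthesize one recording of ``n_cycles`` breath cycles for a subject.

    Each cycle is an inspiration burst and an expiration burst of shaped noise
    separated by low-energy background; the exact sample range of every true
    phase is returned. The phase/background duty cycle is kept below 40% so
    log-variance segmentation has a clean bimodal threshold.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    effects.validate(fs)
    if seed is None:
        seed = zlib.crc32(f"{subject.subject_id}|{route}".encode()) % (2**31)
    rng = np.random.default_rng(seed)

    # subject-level effect draw: a stable per-subject stream (independent of
    # route and of the noise seed) jitters tilt and turbulence gain around
    # the class means, giving the cohort realistic acoustic heterogeneity
    subj_rng = np.random.default_rng(zlib.crc32(subject.subject_id.encode()))
    effects = replace(
        effects,
        tilt_db_per_octave=effects.tilt_db_per_octave
        + effects.tilt_sd_db_per_octave * subj_rng.standard_normal(),
        turb_gain_db=effects.turb_gain_db
        + effects.turb_gain_sd_db * subj_rng.standard_normal(),
    )

    cycle_s = 60.0 / effects.breath_rate_cpm
    insp_s, exp_s = 0.18 * cycle_s, 0.20 * cycle_s
    gap1_s = 0.22 * cycle_s
    gap2_s = cycle_s - insp_s - exp_s - gap1_s
    lead_s = 0.5 * gap2_s

    total = int(round((n_cycles * cycle_s + lead_s) * fs))
    wave = np.zeros(total)
    annotations: list[PhaseAnnotation] = []

    def burst(dur_s: float, kind: str) -> np.ndarray:
        n = int(round(dur_s * fs))
        eff = effects
        if kind == "expiration":
            # expiration slightly darker than inspiration
            eff = replace(effects, tilt_db_per_octave=effects.tilt_db_per_octave - 1.0)
        x = _shaped_noise(rng, n, fs, eff)
        if effects.coupled_triad:
            t = np.arange(n) / fs
            f1, f2 = effects.triad_freqs
            p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
            x = x + effects.triad_amp * (
                np.cos(2 * np.pi * f1 * t + p1)
                + np.cos(2 * np.pi * f2 * t + p2)
                + np.cos(2 * np.pi * (f1 + f2) * t + p1 + p2)
            )
        # raised-cosine attack/decay (50 ms) keeps onset/offset crisp
        ramp = min(int(0.05 * fs), n // 4)
        env = np.ones(n)
        env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[n - ramp:] = env[:ramp][::-1]
        if effects.am_depth > 0:
            t = np.arange(n) / fs
            env = env * (1.0 + effects.am_depth * np.sin(2 * np.pi * 2.0 * t))
        return x * env

    pos = int(lead_s * fs)
    phase_idx = 0
    for _ in range(n_cycles):
        for kind, dur_s, gap_s in (("inspiration", insp_s, gap1_s), ("expiration", exp_s, gap2_s)):
            b = burst(dur_s, kind)
            end = min(pos + len(b), total)
            wave[pos:end] += b[: end - pos]
            annotations.append(PhaseAnnotation(phase_idx, kind, pos, end))
            phase_idx += 1
            pos = end + int(gap_s * fs)

    if noise:
        bg = _background_noise(rng, total, fs)
        phase_rms = np.sqrt(np.mean(np.concatenate(
            [wave[a.start_sample:a.end_sample] ** 2 for a in annotations])))
        bg_rms = phase_rms / 10.0 ** (effects.snr_db / 20.0)
        wave = wave + bg * bg_rms
    return wave, annotations


# ---------------------------------------------------------------------------
# dataset-level helpers and serialization
# ---------------------------------------------------------------------------

def write_wav(path: str | Path, wave: np.ndarray, fs: float = DEFAULT_FS) -> None:
    """Write a mono float-32 WAV, peak-normalized to 0.9 full scale."""
    peak = np.max(np.abs(wave)) + 1e-30
    wavfile.write(str(path), int(fs), (0.9 * wave / peak).astype(np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    fs, data = wavfile.read(str(path))
    x = np.asarray(data, dtype=float)
    if data.dtype == np.int16:
        x = x / 32768.0
    return x, float(fs)


def write_cohort_csv(path: str | Path, records: Iterable[SubjectRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "ahi", "severity", "age", "sex", "bmi", "mps", "nc", "smoke"])
        for r in records:
            w.writerow([
                r.subject_id, f"{r.ahi:.3f}", r.severity_class,
                "" if r.age is None else f"{r.age:.2f}",
                "" if r.sex is None else r.sex,
                "" if r.bmi is None else f"{r.bmi:.2f}",
                "" if r.mps is None else r.mps,
                "" if r.nc is None else f"{r.nc:.2f}",
                "" if r.smoke is None else r.smoke,
            ])


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(SubjectRecord(
                subject_id=row["subject_id"],
                ahi=float(row["ahi"]),
                severity_class=row["severity"],
                age=float(row["age"]) if row["age"] else None,
                sex=row["sex"] or None,
                bmi=float(row["bmi"]) if row["bmi"] else None,
                mps=int(row["mps"]) if row["mps"] else None,
                nc=float(row["nc"]) if row["nc"] else None,
                smoke=row["smoke"] or None,
            ))
    return records


def write_annotations_tsv(path: str | Path,
                          rows: Iterable[tuple[str, str, PhaseAnnotation]]) -> None:
    """BED-like TSV: subject_id, route, phase_index, phase_type, start, end (0-based, half-open)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "route", "phase_index", "phase_type", "start_sample", "end_sample"])
        for sid, route, a in rows:
            w.writerow([sid, route, a.phase_index, a.phase_type, a.start_sample, a.end_sample])


def generate_dataset(
    spec: CohortSpec,
    out_dir: str | Path,
    effects: dict[str, AcousticEffectSpec] | None = None,
    fs: float = DEFAULT_FS,
    routes: tuple[str, ...] = ("nose", "mouth"),
) -> list[SubjectRecord]:
    """Generate cohort CSV, per-subject WAVs and a ground-truth annotation TSV."""
    effects = effects or DEFAULT_EFFECTS
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(spec)
    write_cohort_csv(out / "cohort.csv", records)
    ann_rows = []
    seeds = np.random.SeedSequence(spec.seed).spawn(len(records) * len(routes))
    k = 0
    for rec in records:
        for route in routes:
            seed = int(seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            wave, anns = synthesize_recording(rec, effects[rec.severity_class], fs, route, seed=seed)
            write_wav(out / f"{rec.subject_id}_{route}.wav", wave, fs)
            ann_rows.extend((rec.subject_id, route, a) for a in anns)
    write_annotations_tsv(out / "annotations.tsv", ann_rows)
    return records
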