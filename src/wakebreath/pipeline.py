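"""End-to-end pipeline driver: synth -> preprocess -> spectra -> features ->
select -> train -> evaluate -> report.

The driver is deliberately thin: every stage is a library call, the
configuration is a validated YAML-backed tree, and stage outputs land in a
results directory with a provenance manifest (config hash + seed). Re-running
with an identical config is a cache hit on the final metrics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wakebreath import cohortprep, modelzoo, select, synthgen
from wakebreath.featurebank import FeatureConfig, assemble_feature_table
from wakebreath.preprocess import PreprocessConfig, preprocess_recording
from wakebreath.spectra import build_ci_band, detect_psd_gaps, welch_psd

STAGES = ("synth", "preprocess", "spectra", "features", "select", "train",
          "evaluate", "report")


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending key."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated stage-keyed parameter tree."""

    seed: int = 0
    out_dir: str = "results"
    audio_dir: str | None = None
    cohort_csv: str | None = None
    synth_enabled: bool = True
    n_per_class: int = 20
    missing_rate: float = 0.05
    routes: tuple[str, ...] = ("mouth",)
    feature_families: tuple[str, ...] = ("spectral", "time")
    reference_stream: tuple[str, str] = ("mouth", "inspiration")
    n_acoustic: int = 12
    zoo: tuple[str, ...] = modelzoo.DEMO_ZOO
    n_trials: int = 1
    opt_budget: int = 6
    bags: int = 25
    n_test_repeats: int = 3
    experiments: tuple[str, ...] | None = None  # None = all six

    _KNOWN = {
        "seed", "out_dir", "audio_dir", "cohort_csv", "synth_enabled",
        "n_per_class", "missing_rate", "routes", "feature_families",
        "reference_stream", "n_acoustic", "zoo", "n_trials", "opt_budget",
        "bags", "n_test_repeats", "experiments",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("routes", "feature_families", "zoo", "experiments"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "reference_stream" in d:
            d["reference_stream"] = tuple(d["reference_stream"])
        cfg = cls(**d)
        for z in cfg.zoo:
            if z not in modelzoo.CLASSIFIER_ZOO:
                raise ConfigError(f"unknown classifier config: {z}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    metrics: dict
    out_dir: Path
    cached: bool = False


def _load_or_synth(cfg: PipelineConfig, rng_seed: int):
    if cfg.synth_enabled:
        spec = synthgen.CohortSpec(
            n_per_class={c: cfg.n_per_class for c in synthgen.SEVERITY_CLASSES},
            missing_rate=cfg.missing_rate, seed=rng_seed)
        records = synthgen.generate_cohort(spec)
        waves = {}
        seeds = np.random.SeedSequence(rng_seed).spawn(len(records) * len(cfg.routes))
        k = 0
        for rec in records:
            for route in cfg.routes:
                s = int(seeds[k].generate_state(1)[0] % (2**31))
                k += 1
                wave, _ = synthgen.synthesize_recording(
                    rec, synthgen.DEFAULT_EFFECTS[rec.severity_class],
                    route=route, seed=s)
                waves[(rec.subject_id, route)] = wave
        return records, waves
    if not cfg.cohort_csv or not Path(cfg.cohort_csv).exists():
        raise ConfigError("cohort_csv is missing and synth is disabled")
    if not cfg.audio_dir or not Path(cfg.audio_dir).exists():
        raise ConfigError("audio_dir is missing and synth is disabled")
    records = synthgen.read_cohort_csv(cfg.cohort_csv)
    waves = {}
    for rec in records:
        for route in cfg.routes:
            path = Path(cfg.audio_dir) / f"{rec.subject_id}_{route}.wav"
            if path.exists():
                waves[(rec.subject_id, route)], _ = synthgen.read_wav(path)
    return records, waves


def run_pipeline(cfg: PipelineConfig, until: str = "report") -> PipelineResult:
    """Run the pipeline up to ``until`` (default: everything).

    Writes metrics.json/metrics.csv plus a provenance manifest to
    ``cfg.out_dir``; an existing manifest with the same config hash makes the
    run a cache hit.
    """
    if until not in STAGES:
        raise ConfigError(f"unknown stage {until!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    metrics_path = out / "metrics.json"
    chash = cfg.content_hash()
    if manifest_path.exists() and metrics_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash and manifest.get("until") == until:
            return PipelineResult(json.loads(metrics_path.read_text()), out, cached=True)

    fs = synthgen.DEFAULT_FS
    records, waves = _load_or_synth(cfg, cfg.seed)
    stage_out: dict = {"n_subjects": len(records)}
    if until == "synth":
        return _finish(cfg, out, stage_out, until)

    # preprocess: segmented/filtered/normalized phases + per-stream mean PSDs
    pre_cfg = PreprocessConfig()
    phases_by_subject = {}
    psd_cache: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    for rec in records:
        phases = []
        for route in cfg.routes:
            w = waves.get((rec.subject_id, route))
            if w is None:
                continue
            phases.extend(preprocess_recording(w, fs, rec.subject_id, route, pre_cfg))
        phases_by_subject[rec.subject_id] = phases
        for route in cfg.routes:
            for ptype in ("inspiration", "expiration"):
                sel = [p for p in phases if p.kept and p.route == route
                       and p.phase_type == ptype]
                ests = [welch_psd(p.samples, fs) for p in sel
                        if p.samples.size >= 1024]
                if ests:
                    psd_cache[(rec.subject_id, route, ptype)] = (
                        ests[0].freqs, np.mean([e.psd for e in ests], axis=0))
    stage_out["n_phases"] = int(sum(len(v) for v in phases_by_subject.values()))
    if until == "preprocess":
        return _finish(cfg, out, stage_out, until)

    # cohort prep: imputation + one 85/15 split (first shuffle)
    records = cohortprep.impute_anthropometrics(records)
    plans = cohortprep.make_train_test_split(records, seed=cfg.seed, n_shuffles=1)
    plan = plans[0]
    train_ids, test_ids = set(plan.train_ids), set(plan.test_ids)
    rec_by_id = {r.subject_id: r for r in records}

    # spectra: per-experiment CI-band gap detection on the reference stream,
    # training subjects only
    route_ref, ptype_ref = cfg.reference_stream
    exp_specs = [e for e in modelzoo.EXPERIMENTS
                 if cfg.experiments is None or e.name in cfg.experiments]
    gap_bands_per_exp: dict[str, tuple[tuple[float, float], ...]] = {}
    for exp in exp_specs:
        ref_psds, tgt_psds, freqs = [], [], None
        for sid in plan.train_ids:
            key = (sid, route_ref, ptype_ref)
            if key not in psd_cache:
                continue
            f, p = psd_cache[key]
            freqs = f
            cls = rec_by_id[sid].severity_class
            if cls == exp.negative_class:
                ref_psds.append(p)
            elif cls == exp.positive_class:
                tgt_psds.append(p)
        bands: tuple[tuple[float, float], ...] = ()
        if len(ref_psds) >= 2 and tgt_psds and freqs is not None:
            band = build_ci_band(np.vstack(ref_psds))
            band.freqs = freqs
            gaps = detect_psd_gaps(np.mean(tgt_psds, axis=0), band)
            bands = tuple((fa, fb) for _, _, fa, fb, _ in gaps.psd_gaps[:4])
        gap_bands_per_exp[exp.name] = bands
    stage_out["gap_bands"] = {k: list(map(list, v))
                              for k, v in gap_bands_per_exp.items()}
    if until == "spectra":
        return _finish(cfg, out, stage_out, until)

    # features: base table once; gap-band spectral features from cached PSDs
    base_cfg = FeatureConfig(families=cfg.feature_families)
    table = assemble_feature_table(phases_by_subject, base_cfg)
    table.to_csv(out / "features.csv")
    if until == "features":
        return _finish(cfg, out, stage_out, until)

    from wakebreath.featurebank.spectral import spectral_features

    results: dict[str, dict] = {}
    for exp in exp_specs:
        ids = [r.subject_id for r in records
               if r.severity_class in (exp.class_a, exp.class_b)]
        frame = table.frame.loc[ids].copy()
        for i, band in enumerate(gap_bands_per_exp[exp.name]):
            cols = {}
            for sid in ids:
                key = (sid, route_ref, ptype_ref)
                if key in psd_cache:
                    f, p = psd_cache[key]
                    cols[sid] = spectral_features(f, p, band=band,
                                                  prefix=f"gapband{i}_")
            gap_df = pd.DataFrame.from_dict(cols, orient="index")
            frame = frame.join(gap_df)
        y = np.array([rec_by_id[sid].severity_class for sid in ids])
        tr = [sid for sid in ids if sid in train_ids]
        te = [sid for sid in ids if sid in test_ids]
        y_tr = np.array([rec_by_id[sid].severity_class for sid in tr])
        y_te = np.array([rec_by_id[sid].severity_class for sid in te])

        sel = select.select_features(
            frame.loc[tr], y_tr, [rec_by_id[sid] for sid in tr],
            n_acoustic=cfg.n_acoustic, seed=cfg.seed)
        acoustic_cols = sel.wrapper_survivors
        X_tr_ac = sel.normalization.transform(frame.loc[tr])[acoustic_cols]
        X_te_ac = sel.normalization.transform(frame.loc[te])[acoustic_cols]
        fused_tr = select.fuse_with_anthropometrics(
            X_tr_ac, [rec_by_id[sid] for sid in tr]).frame
        fused_te = select.fuse_with_anthropometrics(
            X_te_ac, [rec_by_id[sid] for sid in te]).frame
        X_tr = np.nan_to_num(fused_tr.to_numpy(dtype=float), nan=0.0)
        X_te = np.nan_to_num(fused_te.to_numpy(dtype=float), nan=0.0)
        if until == "select":
            results[exp.name] = {"n_features": int(X_tr.shape[1])}
            continue

        trials = {}
        for zi, zname in enumerate(cfg.zoo):
            factory, space = modelzoo.CLASSIFIER_ZOO[zname]
            trials[zname] = modelzoo.run_trials(
                factory, space, X_tr, y_tr, exp.positive_class,
                n_trials=cfg.n_trials, budget=cfg.opt_budget, B=cfg.bags,
                seed=cfg.seed + 7 * zi + 1)
        final_name, final = modelzoo.select_final(trials)
        entry = {
            "classifier": final_name,
            "oob_accuracy": final.oob.accuracy,
            "oob_sensitivity": final.oob.sensitivity,
            "oob_specificity": final.oob.specificity,
            "n_features": int(X_tr.shape[1]),
        }
        if until in ("evaluate", "report") and len(te) > 0:
            factory, _ = modelzoo.CLASSIFIER_ZOO[final_name]
            _, agg = modelzoo.evaluate_test(
                factory, final.params, X_tr, y_tr, X_te, y_te,
                exp.positive_class, n_repeats=cfg.n_test_repeats, B=cfg.bags,
                seed=cfg.seed)
            entry.update({"test_" + k: v for k, v in agg.items()})
        results[exp.name] = entry
    stage_out["experiments"] = results
    return _finish(cfg, out, stage_out, until)


def _finish(cfg: PipelineConfig, out: Path, metrics: dict, until: str
            ) -> PipelineResult:
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    if "experiments" in metrics:
        pd.DataFrame.from_dict(metrics["experiments"], orient="index").to_csv(
            out / "metrics.csv", index_label="experiment")
    (out / "manifest.json").write_text(json.dumps({
        "config_hash": cfg.content_hash(), "seed": cfg.seed, "until": until,
        "config": asdict(cfg),
    }, indent=1, sort_keys=True, default=list))
    return PipelineResult(metrics, out, cached=False)


def report(out_dir: str | Path) -> pd.DataFrame:
    """Unified metrics table of a finished run."""
    metrics = json.loads((Path(out_dir) / "metrics.json").read_text())
    if "experiments" not in metrics:
        raise FileNotFoundError("run has no experiment metrics (stage incomplete)")
    return pd.DataFrame.from_dict(metrics["experiments"], orient="index")
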