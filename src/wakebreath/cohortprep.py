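"""Cohort preparation: severity-specific kNN imputation and leakage-safe splits.

* Missing anthropometrics are imputed with neighbours drawn only from the same
  severity class (preserving internal group distributions).
* The 85/15 train/test split is stratified by severity, repeated with
  reshuffles, and the test set's continuous variables are checked to fall
  within one SD of the overall means.
* The custom K-fold balances folds jointly over severity and the clinical
  confounder thresholds: age >= 50, BMI >= 35, NC > 40, sex, Mallampati score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from statistics import mode
from typing import Sequence

import numpy as np

from wakebreath.synthgen import SubjectRecord

CONTINUOUS = ("age", "bmi", "nc")
CATEGORICAL = ("sex", "mps", "smoke")

#: columns that must never appear on the feature side of a design matrix
LABEL_COLUMNS = ("ahi", "severity", "severity_class")


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    shuffle_index: int
    seed: int

    def to_json(self) -> dict:
        return {"train_ids": list(self.train_ids), "test_ids": list(self.test_ids),
                "shuffle_index": self.shuffle_index, "seed": self.seed}


@dataclass(frozen=True)
class FoldPlan:
    assignments: dict[str, int]
    k: int
    seed: int
    strata: dict[str, str] = field(default_factory=dict)

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignments.items() if f == fold]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"assignments": self.assignments, "k": self.k, "seed": self.seed}))


def assert_no_label_leakage(columns: Sequence[str]) -> None:
    """Guard: AHI/severity must never enter a feature matrix."""
    bad = [c for c in columns if c.lower() in LABEL_COLUMNS]
    if bad:
        raise ValueError(f"label columns {bad} found on the feature side")


def impute_anthropometrics(records: Sequence[SubjectRecord], k: int = 5,
                           feature_weights: dict[str, float] | None = None
                           ) -> list[SubjectRecord]:
    """Severity-specific kNN imputation of missing anthropometrics.

    Distances are computed per severity class on z-scored observed continuous
    fields plus 0/1 mismatch indicators for categoricals, restricted to
    mutually observed fields. Continuous fields are imputed with the k-nearest
    neighbours' mean, categoricals with their mode. Observed values are never
    altered; a class with fewer than k complete donors for a field falls back
    to the class mean/mode with a warning.
    """
    weights = feature_weights or {}
    out = [replace(r) if hasattr(r, "__dataclass_fields__") else r for r in records]
    by_class: dict[str, list[SubjectRecord]] = {}
    for r in out:
        by_class.setdefault(r.severity_class, []).append(r)

    for cls, members in by_class.items():
        stats = {}
        for f in CONTINUOUS:
            vals = np.array([getattr(r, f) for r in members if getattr(r, f) is not None],
                            dtype=float)
            stats[f] = (float(vals.mean()), float(vals.std() + 1e-12)) if vals.size else (0.0, 1.0)

        def distance(a: SubjectRecord, b: SubjectRecord) -> float:
            d, n = 0.0, 0
            for f in CONTINUOUS:
                va, vb = getattr(a, f), getattr(b, f)
                if va is not None and vb is not None:
                    mu, sd = stats[f]
                    d += weights.get(f, 1.0) * ((va - vb) / sd) ** 2
                    n += 1
            for f in CATEGORICAL:
                va, vb = getattr(a, f), getattr(b, f)
                if va is not None and vb is not None:
                    d += weights.get(f, 1.0) * float(va != vb)
                    n += 1
            return d / n if n else float("inf")

        for r in members:
            for f in CONTINUOUS + CATEGORICAL:
                if getattr(r, f) is not None:
                    continue
                donors = [m for m in members if m is not r and getattr(m, f) is not None]
                if len(donors) < k:
                    warnings.warn(f"{cls}: fewer than {k} donors for {f}; class fallback")
                    pool = donors
                else:
                    pool = sorted(donors, key=lambda m: distance(r, m))[:k]
                if not pool:
                    continue
                vals = [getattr(m, f) for m in pool]
                if f in CONTINUOUS:
                    setattr(r, f, float(np.mean(vals)))
                else:
                    setattr(r, f, mode(vals))
    return out


def _test_count(n: int, ratio: float) -> int:
    # round-half-to-even reproduces the published per-class test sizes
    return max(int(round((1.0 - ratio) * n)), 1)


def make_train_test_split(
    records: Sequence[SubjectRecord],
    ratio: float = 0.85,
    n_shuffles: int = 10,
    balance_vars: tuple[str, ...] = CONTINUOUS,
    seed: int = 0,
    max_attempts: int = 200,
) -> list[SplitPlan]:
    """Stratified 85/15 splits, reshuffled ``n_shuffles`` times.

    Per severity class the test count is round((1-ratio)*n). Candidate test
    sets are redrawn until the continuous balance check passes: test-set
    means of ``balance_vars`` within one SD of the overall means. If no
    candidate passes within ``max_attempts`` the best one is returned with a
    warning.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for r in records:
        by_class.setdefault(r.severity_class, []).append(r.subject_id)
    rec_by_id = {r.subject_id: r for r in records}

    overall = {}
    for v in balance_vars:
        vals = np.array([getattr(r, v) for r in records if getattr(r, v) is not None],
                        dtype=float)
        overall[v] = (float(vals.mean()), float(vals.std())) if vals.size else (0.0, 1.0)

    def imbalance(test_ids: list[str]) -> float:
        worst = 0.0
        for v in balance_vars:
            vals = np.array([getattr(rec_by_id[i], v) for i in test_ids
                             if getattr(rec_by_id[i], v) is not None], dtype=float)
            if vals.size == 0:
                continue
            mu, sd = overall[v]
            worst = max(worst, abs(float(vals.mean()) - mu) / max(sd, 1e-12))
        return worst

    plans = []
    for shuffle in range(n_shuffles):
        best, best_score = None, float("inf")
        for _ in range(max_attempts):
            test_ids: list[str] = []
            for cls, ids in by_class.items():
                take = _test_count(len(ids), ratio)
                test_ids.extend(rng.choice(ids, size=take, replace=False))
            score = imbalance(test_ids)
            if score < best_score:
                best, best_score = test_ids, score
            if score <= 1.0:
                break
        if best_score > 1.0:
            warnings.warn(f"shuffle {shuffle}: balance check failed "
                          f"(worst deviation {best_score:.2f} SD); best candidate kept")
        test_set = set(best)  # type: ignore[arg-type]
        train_ids = tuple(r.subject_id for r in records if r.subject_id not in test_set)
        plans.append(SplitPlan(train_ids=train_ids, test_ids=tuple(best),  # type: ignore[arg-type]
                               shuffle_index=shuffle, seed=seed))
    return plans


def _stratum_key(r: SubjectRecord) -> str:
    return "|".join([
        r.severity_class,
        "age>=50" if (r.age or 0) >= 50 else "age<50",
        "bmi>=35" if (r.bmi or 0) >= 35 else "bmi<35",
        "nc>40" if (r.nc or 0) > 40 else "nc<=40",
        str(r.sex),
        f"mps{r.mps}",
    ])


def make_kfold(records: Sequence[SubjectRecord], k: int = 3, seed: int = 0) -> FoldPlan:
    """Jointly stratified K-fold over severity x anthropometric thresholds.

    Greedy balanced assignment: strata are processed largest first; each
    member goes to the fold minimizing (count within this stratum, count
    within this severity class, total fold count). Per-stratum fold counts
    therefore differ by at most 1, and per-class fold sizes stay near-equal.
    """
    rng = np.random.default_rng(seed)
    strata: dict[str, list[SubjectRecord]] = {}
    for r in records:
        strata.setdefault(_stratum_key(r), []).append(r)

    assignments: dict[str, int] = {}
    stratum_of: dict[str, str] = {}
    per_class = {r.severity_class: np.zeros(k, dtype=int) for r in records}
    totals = np.zeros(k, dtype=int)
    for key in sorted(strata, key=lambda s: -len(strata[s])):
        members = strata[key]
        order = rng.permutation(len(members))
        counts = np.zeros(k, dtype=int)
        for i in order:
            r = members[int(i)]
            cost = [(counts[f], per_class[r.severity_class][f], totals[f], f)
                    for f in range(k)]
            f = min(cost)[3]
            assignments[r.subject_id] = f
            stratum_of[r.subject_id] = key
            counts[f] += 1
            per_class[r.severity_class][f] += 1
            totals[f] += 1
    return FoldPlan(assignments=assignments, k=k, seed=seed, strata=stratum_of)
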