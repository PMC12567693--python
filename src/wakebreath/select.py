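"""Adaptive feature normalization and three-stage feature selection.

Normalization: candidate methods (z-score, min-max, robust median/IQR,
rank/quantile) are fitted on training data only; the method maximizing the
total mutual information between normalized features and the binary label
(equal-frequency binning) wins.

Selection: filter (Welch t-test) -> embedded (Shapley-attribution ranking of
a gradient-boosted-tree scorer) -> wrapper (recursive feature elimination
driven by RUSBoost importances), then fusion with the anthropometric block.
The stages are nested: each stage only sees the previous stage's survivors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.tree import DecisionTreeClassifier

from wakebreath.cohortprep import assert_no_label_leakage
from wakebreath.featurebank import FeatureTable
from wakebreath.shapley import mean_abs_attribution
from wakebreath.synthgen import SubjectRecord

NORMALIZATION_CANDIDATES = ("zscore", "minmax", "robust", "rank")


@dataclass
class NormalizationChoice:
    """A fitted, frozen normalization: parameters come from training only."""

    method: str
    params: dict = field(default_factory=dict)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        p = self.params
        if self.method == "zscore":
            return (X - p["mean"]) / p["sd"]
        if self.method == "minmax":
            return (X - p["min"]) / p["range"]
        if self.method == "robust":
            return (X - p["median"]) / p["iqr"]
        if self.method == "rank":
            out = {}
            for c in X.columns:
                ref = np.asarray(p["sorted"][c])
                out[c] = np.searchsorted(ref, X[c].to_numpy(), side="right") / max(len(ref), 1)
            return pd.DataFrame(out, index=X.index)
        raise ValueError(f"unknown method {self.method!r}")


def fit_normalizer(X: pd.DataFrame, method: str) -> NormalizationChoice:
    eps = 1e-12
    if method == "zscore":
        params = {"mean": X.mean(), "sd": X.std(ddof=0).clip(lower=eps)}
    elif method == "minmax":
        rng = (X.max() - X.min()).clip(lower=eps)
        params = {"min": X.min(), "range": rng}
    elif method == "robust":
        iqr = (X.quantile(0.75) - X.quantile(0.25)).clip(lower=eps)
        params = {"median": X.median(), "iqr": iqr}
    elif method == "rank":
        params = {"sorted": {c: np.sort(X[c].dropna().to_numpy()) for c in X.columns}}
    else:
        raise ValueError(f"unknown method {method!r}")
    return NormalizationChoice(method=method, params=params)


def mutual_information_bits(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """MI (bits) between a continuous feature and a discrete label, with
    equal-frequency binning of the feature. Constant features give 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    ok = np.isfinite(x)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.all(x == x[0]):
        return 0.0
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:
        return 0.0
    bins = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)
    classes = np.unique(y)
    n = x.size
    mi = 0.0
    for b in np.unique(bins):
        pb = np.mean(bins == b)
        for c in classes:
            pbc = np.mean((bins == b) & (y == c))
            pc = np.mean(y == c)
            if pbc > 0:
                mi += pbc * np.log2(pbc / (pb * pc))
    return float(max(mi, 0.0))


def choose_normalization(X: pd.DataFrame, y: np.ndarray,
                         candidates: Sequence[str] = NORMALIZATION_CANDIDATES,
                         n_bins: int = 10) -> NormalizationChoice:
    """Pick the candidate maximizing summed per-feature MI with the label.

    Ties break by candidate order. The fitted parameters are frozen for
    application to test data.
    """
    best: NormalizationChoice | None = None
    best_score = -np.inf
    for method in candidates:
        norm = fit_normalizer(X, method)
        Xn = norm.transform(X)
        score = sum(mutual_information_bits(Xn[c].to_numpy(), y, n_bins)
                    for c in Xn.columns)
        if score > best_score + 1e-12:
            best, best_score = norm, score
    assert best is not None
    return best


def ttest_filter(X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Welch two-sample t-test per feature; keep p < alpha (original order)."""
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("t-test filter requires binary labels")
    a, b = (np.asarray(y) == classes[0]), (np.asarray(y) == classes[1])
    survivors = []
    for c in X.columns:
        v = X[c].to_numpy(dtype=float)
        va, vb = v[a], v[b]
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if va.size < 2 or vb.size < 2 or (np.std(va) == 0 and np.std(vb) == 0):
            continue
        _, p = stats.ttest_ind(va, vb, equal_var=False)
        if np.isfinite(p) and p < alpha:
            survivors.append(c)
    return survivors


def shap_rank(X: pd.DataFrame, y: np.ndarray, model=None, n_background: int = 50,
              n_permutations: int = 4, max_rows: int = 60,
              seed: int = 0) -> list[str]:
    """Features ranked by mean |Shapley attribution| of a tree-ensemble scorer.

    The scorer (default: 200-round depth-3 gradient-boosted trees) is fitted
    on the training rows; attributions are interventional Shapley values of
    its decision function against a background subsample.
    """
    rng = np.random.default_rng(seed)
    model = model or GradientBoostingClassifier(n_estimators=200, max_depth=3,
                                                random_state=seed)
    Xv = X.to_numpy(dtype=float)
    Xv = np.nan_to_num(Xv, nan=0.0)
    model.fit(Xv, y)
    bg = Xv[rng.choice(Xv.shape[0], size=min(n_background, Xv.shape[0]), replace=False)]
    imp = mean_abs_attribution(model.decision_function, Xv, bg,
                               n_permutations=n_permutations, max_rows=max_rows, rng=rng)
    order = np.argsort(-imp, kind="stable")
    return [X.columns[i] for i in order]


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosting with per-round random undersampling of the majority class.

    AdaBoost-style reweighting on the full training set; each round's base
    stump is fitted on a class-balanced random undersample drawn according to
    the current weights. ``feature_importances_`` is the alpha-weighted mean
    of the stumps' impurity importances.
    """

    def __init__(self, n_estimators: int = 100, max_depth: int = 1,
                 learning_rate: float = 1.0, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("binary labels required")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        w = (np.ones(n) if sample_weight is None else
             np.asarray(sample_weight, dtype=float).copy())
        w /= w.sum()
        minority = int(np.argmin(np.bincount(yi)))
        n_min = int(np.sum(yi == minority))
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        for _ in range(self.n_estimators):
            idx_min = np.flatnonzero(yi == minority)
            idx_maj = np.flatnonzero(yi != minority)
            p = w[idx_maj] / w[idx_maj].sum()
            take = rng.choice(idx_maj, size=min(n_min, idx_maj.size), replace=False,
                              p=p) if idx_maj.size > n_min else idx_maj
            idx = np.concatenate([idx_min, take])
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31)))
            tree.fit(X[idx], yi[idx], sample_weight=w[idx] * n)
            pred = tree.predict(X)
            err = float(np.sum(w[pred != yi]))
            err = min(max(err, 1e-10), 1 - 1e-10)
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / err)
            if alpha <= 0:
                alpha = 1e-3  # keep the round with negligible weight
            w *= np.exp(alpha * (2.0 * (pred != yi) - 1.0))
            w /= w.sum()
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
        imps = np.array([t.feature_importances_ for t in self.estimators_])
        a = np.array(self.alphas_)
        self.feature_importances_ = (a[:, None] * imps).sum(axis=0) / a.sum()
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        score = np.zeros(X.shape[0])
        for a, t in zip(self.alphas_, self.estimators_):
            score += a * (2.0 * t.predict(X) - 1.0)
        return score

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def rfe_rusboost(X: pd.DataFrame, y: np.ndarray, target_k: int,
                 step: float = 0.1, n_estimators: int = 100,
                 seed: int = 0) -> list[str]:
    """Recursive feature elimination with RUSBoost importances.

    Each iteration drops the ``step`` fraction (at least 1) of the
    lowest-importance features until ``target_k`` remain. Survivors are
    returned in the input column order.
    """
    cols = list(X.columns)
    if target_k >= len(cols):
        return cols
    Xv = np.nan_to_num(X.to_numpy(dtype=float), nan=0.0)
    active = np.arange(len(cols))
    rng = np.random.default_rng(seed)
    while active.size > target_k:
        model = RUSBoostClassifier(n_estimators=n_estimators,
                                   random_state=int(rng.integers(2**31)))
        model.fit(Xv[:, active], y)
        drop = min(max(int(np.ceil(step * active.size)), 1), active.size - target_k)
        order = np.argsort(model.feature_importances_, kind="stable")
        active = np.delete(active, order[:drop])
    keep = set(active.tolist())
    return [c for i, c in enumerate(cols) if i in keep]


ANTHRO_BLOCK = ("bmi", "age", "sex", "smoke", "nc", "mps")


def anthropometric_block(records: Sequence[SubjectRecord],
                         seventh: str = "sex_bmi") -> pd.DataFrame:
    """7-column anthropometric block (sex/smoke as 0/1, MPS as integer).

    Six variables are named in the study protocol; the seventh slot is
    configurable and defaults to the sex x BMI interaction.
    """
    rows = {}
    for r in records:
        sex01 = float(r.sex == "M") if r.sex is not None else np.nan
        smoke01 = float(r.smoke == "yes") if r.smoke is not None else np.nan
        row = {
            "bmi": np.nan if r.bmi is None else float(r.bmi),
            "age": np.nan if r.age is None else float(r.age),
            "sex": sex01,
            "smoke": smoke01,
            "nc": np.nan if r.nc is None else float(r.nc),
            "mps": np.nan if r.mps is None else float(r.mps),
        }
        if seventh == "sex_bmi":
            row["sex_x_bmi"] = row["sex"] * row["bmi"]
        rows[r.subject_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def fuse_with_anthropometrics(selected: pd.DataFrame,
                              records: Sequence[SubjectRecord],
                              seventh: str = "sex_bmi") -> FeatureTable:
    """Append the anthropometric block to the selected acoustic features.

    Columns are ordered acoustic-then-anthropometric; names must be unique.
    """
    anthro = anthropometric_block(records, seventh).loc[list(selected.index)]
    dup = set(selected.columns) & set(anthro.columns)
    if dup:
        raise ValueError(f"duplicate column names {sorted(dup)}")
    fused = pd.concat([selected, anthro], axis=1)
    assert_no_label_leakage(fused.columns)
    return FeatureTable(frame=fused)


@dataclass
class SelectionResult:
    """Nested per-stage survivors plus the final fused feature set."""

    normalization: NormalizationChoice
    filter_survivors: list[str]
    embedded_ranking: list[str]
    wrapper_survivors: list[str]
    fused: FeatureTable
    seed: int = 0

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "normalization": self.normalization.method,
            "filter": self.filter_survivors,
            "embedded": self.embedded_ranking,
            "wrapper": self.wrapper_survivors,
            "final": list(self.fused.feature_names),
            "seed": self.seed,
        }, indent=1))


def select_features(
    features: pd.DataFrame,
    y: np.ndarray,
    records: Sequence[SubjectRecord],
    n_acoustic: int = 34,
    alpha: float = 0.05,
    embedded_keep: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Full pipeline: normalize -> t-test -> Shapley rank -> RFE -> fuse.

    ``n_acoustic`` acoustic survivors plus the 7-column anthropometric block
    give the default fused width of 41.
    """
    assert_no_label_leakage(features.columns)
    X = features.dropna(axis=1, how="all")
    norm = choose_normalization(X, y)
    Xn = norm.transform(X)
    filt = ttest_filter(Xn, y, alpha)
    if len(filt) < n_acoustic:
        # backfill by ascending p-value so the fused-width contract holds
        warnings.warn("t-test filter left fewer survivors than the acoustic "
                      "budget; backfilling by p-value")
        pvals = {}
        classes = np.unique(y)
        a, b = (y == classes[0]), (y == classes[1])
        for c in Xn.columns:
            if c in filt:
                continue
            v = Xn[c].to_numpy(dtype=float)
            va, vb = v[a], v[b]
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            if va.size < 2 or vb.size < 2:
                continue
            _, p = stats.ttest_ind(va, vb, equal_var=False)
            pvals[c] = p if np.isfinite(p) else 1.0
        extra = sorted(pvals, key=pvals.get)[: n_acoustic - len(filt)]
        filt = filt + extra
    ranked = shap_rank(Xn[filt], y, seed=seed)
    keep = ranked[: embedded_keep or max(2 * n_acoustic, 10)]
    if len(keep) > n_acoustic:
        wrapped = rfe_rusboost(Xn[keep], y, target_k=n_acoustic, seed=seed)
    else:
        wrapped = list(keep)
    fused = fuse_with_anthropometrics(Xn[wrapped], records)
    return SelectionResult(norm, filt, ranked, wrapped, fused, seed)
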