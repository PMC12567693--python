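"""Pairwise severity experiments: classifier zoo, Bayesian tuning, B=50
bagging with out-of-bag (OOB) validation, repeated trials, final selection
and repeated test evaluation.

Six binary experiments compare the severity classes pairwise; for each, every
classifier configuration is tuned by Bayesian optimization of the 5-fold
stratified CV misclassification rate, bagged over 50 stratified bootstrap
resamples, and scored by OOB majority-vote metrics. The classifier with the
best OOB accuracy becomes the experiment's final model; the held-out test set
is touched only afterwards.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from wakebreath.bayesopt import OptResult, Param, minimize_ei_plus
from wakebreath.select import RUSBoostClassifier
from wakebreath.synthgen import SEVERITY_CLASSES

# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

SEVERITY_ORDER = {c: i for i, c in enumerate(SEVERITY_CLASSES)}


@dataclass(frozen=True)
class ExperimentSpec:
    """One pairwise severity comparison; positive = the more severe class."""

    class_a: str
    class_b: str
    feature_set_id: str = "default"

    def __post_init__(self):
        if self.class_a == self.class_b:
            raise ValueError("classes must differ")

    @property
    def positive_class(self) -> str:
        return max((self.class_a, self.class_b), key=SEVERITY_ORDER.__getitem__)

    @property
    def negative_class(self) -> str:
        return min((self.class_a, self.class_b), key=SEVERITY_ORDER.__getitem__)

    @property
    def name(self) -> str:
        return f"{self.negative_class}_vs_{self.positive_class}"


#: the six pairwise experiments, in protocol order
EXPERIMENTS: tuple[ExperimentSpec, ...] = (
    ExperimentSpec("NonOSA", "Mild"),
    ExperimentSpec("NonOSA", "Moderate"),
    ExperimentSpec("NonOSA", "Severe"),
    ExperimentSpec("Mild", "Moderate"),
    ExperimentSpec("Mild", "Severe"),
    ExperimentSpec("Moderate", "Severe"),
)

# ---------------------------------------------------------------------------
# classifier zoo
# ---------------------------------------------------------------------------


def _svm(kernel: str, degree: int | None = None):
    def factory(params: dict):
        kw = dict(kernel=kernel, C=params.get("C", 1.0), probability=False)
        if kernel in ("rbf", "poly"):
            kw["gamma"] = params.get("gamma", "scale")
        if degree is not None:
            kw["degree"] = degree
        return SVC(**kw)
    return factory


def _space_C(log_lo=1e-3, log_hi=1e3):
    return [Param("C", "log", (log_lo, log_hi))]


def _space_C_gamma():
    return _space_C() + [Param("gamma", "log", (1e-4, 1e1))]


#: classifier families: name -> (factory(params) -> estimator, search space).
#: Search spaces are documented defaults; the study protocol does not print
#: usable per-family ranges.
CLASSIFIER_ZOO: dict[str, tuple[Callable[[dict], object], list[Param]]] = {
    "decision_tree": (
        lambda p: DecisionTreeClassifier(max_depth=p.get("max_depth", 5),
                                         min_samples_leaf=p.get("min_samples_leaf", 1),
                                         random_state=0),
        [Param("max_depth", "int", (1, 12)), Param("min_samples_leaf", "int", (1, 10))]),
    "naive_bayes": (lambda p: GaussianNB(var_smoothing=p.get("var_smoothing", 1e-9)),
                    [Param("var_smoothing", "log", (1e-12, 1e-3))]),
    "logistic_l1": (
        lambda p: LogisticRegression(l1_ratio=1.0, C=p.get("C", 1.0), solver="saga",
                                     max_iter=3000),
        _space_C()),
    "logistic_l2": (
        lambda p: LogisticRegression(C=p.get("C", 1.0), max_iter=2000),
        _space_C()),
    "knn": (lambda p: KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5)),
            [Param("n_neighbors", "int", (1, 25))]),
    "lda": (lambda p: LinearDiscriminantAnalysis(), []),
    "qda": (lambda p: QuadraticDiscriminantAnalysis(reg_param=p.get("reg_param", 0.0)),
            [Param("reg_param", "uniform", (0.0, 1.0))]),
    "svm_linear": (_svm("linear"), _space_C()),
    "svm_rbf": (_svm("rbf"), _space_C_gamma()),
    "svm_poly3": (_svm("poly", 3), _space_C_gamma()),
    "svm_poly5": (_svm("poly", 5), _space_C_gamma()),
    "svm_poly7": (_svm("poly", 7), _space_C_gamma()),
    "svm_poly9": (_svm("poly", 9), _space_C_gamma()),
    "random_forest": (
        lambda p: RandomForestClassifier(n_estimators=p.get("n_estimators", 200),
                                         max_depth=p.get("max_depth", 8), random_state=0),
        [Param("n_estimators", "int", (100, 500)), Param("max_depth", "int", (2, 16))]),
    "bagged_trees": (
        lambda p: BaggingClassifier(DecisionTreeClassifier(max_depth=p.get("max_depth", 8),
                                                           random_state=0),
                                    n_estimators=p.get("n_estimators", 50), random_state=0),
        [Param("n_estimators", "int", (20, 100)), Param("max_depth", "int", (2, 16))]),
    "gradient_boosting": (
        lambda p: GradientBoostingClassifier(n_estimators=p.get("n_estimators", 100),
                                             learning_rate=p.get("learning_rate", 0.1),
                                             max_depth=3, random_state=0),
        [Param("n_estimators", "int", (50, 300)), Param("learning_rate", "log", (0.01, 0.5))]),
    "rusboost": (
        lambda p: RUSBoostClassifier(n_estimators=p.get("n_estimators", 100), random_state=0),
        [Param("n_estimators", "int", (50, 200))]),
    "subspace_knn": (
        lambda p: BaggingClassifier(KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5)),
                                    n_estimators=30, max_features=0.5, bootstrap=False,
                                    random_state=0),
        [Param("n_neighbors", "int", (1, 15))]),
    "shallow_nn": (
        lambda p: MLPClassifier(hidden_layer_sizes=(p.get("width", 32),),
                                alpha=p.get("alpha", 1e-4), max_iter=500, random_state=0),
        [Param("width", "int", (8, 64)), Param("alpha", "log", (1e-6, 1e-1))]),
    "deep_nn": (
        lambda p: MLPClassifier(hidden_layer_sizes=(p.get("width", 32),) * 3,
                                alpha=p.get("alpha", 1e-4), max_iter=500, random_state=0),
        [Param("width", "int", (8, 64)), Param("alpha", "log", (1e-6, 1e-1))]),
}

#: small zoo used by the demo pipeline
DEMO_ZOO = ("lda", "logistic_l2", "random_forest", "svm_rbf")


# ---------------------------------------------------------------------------
# CV loss and tuning
# ---------------------------------------------------------------------------


def cv_loss(factory: Callable[[dict], object], params: dict, X: np.ndarray,
            y: np.ndarray, k: int = 5, seed: int = 0) -> float:
    """Mean misclassification rate under stratified k-fold CV, in [0, 1]."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    k = min(k, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))
    if k < 2:
        return 1.0
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        model = factory(params)
        try:
            model.fit(X[tr], y[tr])
            pred = model.predict(X[te])
        except Exception:
            return 1.0
        errs.append(float(np.mean(pred != y[te])))
    return float(np.mean(errs))


def bayes_opt(factory: Callable[[dict], object], space: Sequence[Param],
              X: np.ndarray, y: np.ndarray, budget: int = 50, k: int = 5,
              seed: int = 0) -> OptResult:
    """Tune ``factory`` hyperparameters by EI+ Bayesian optimization of cv_loss."""
    return minimize_ei_plus(lambda p: cv_loss(factory, p, X, y, k, seed),
                            space, budget=budget, seed=seed)


# ---------------------------------------------------------------------------
# bagging with OOB validation
# ---------------------------------------------------------------------------


@dataclass
class BaggedEnsemble:
    """B bagged learners with their bootstrap membership matrix."""

    learners: list
    membership: np.ndarray  # (N, B) int: draw count of subject i in resample b
    classes: np.ndarray
    positive_class: object
    seed: int = 0

    @property
    def n_learners(self) -> int:
        return len(self.learners)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "BaggedEnsemble":
        return pickle.loads(Path(path).read_bytes())


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of one stratified bootstrap resample: per-class counts exact."""
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def fit_bagged(factory: Callable[[dict], object], params: dict, X: np.ndarray,
               y: np.ndarray, positive_class, B: int = 50, stratified: bool = True,
               class_weighted: bool = True, seed: int = 0) -> BaggedEnsemble:
    """Train B bootstrap learners (|D_b| = N, resampled with replacement).

    Stratified mode preserves the original class counts in each resample;
    class-weighted mode passes inverse-frequency sample weights to learners
    that accept them (cost-sensitive loss).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    freq = dict(zip(classes, counts / n))
    learners = []
    membership = np.zeros((n, B), dtype=int)
    for b in range(B):
        idx = (_stratified_bootstrap(y, rng) if stratified
               else rng.integers(0, n, size=n))
        membership[:, b] = np.bincount(idx, minlength=n)
        model = factory(params)
        if hasattr(model, "random_state"):
            try:
                model.set_params(random_state=int(rng.integers(2**31)))
            except (ValueError, AttributeError):
                pass
        if class_weighted:
            sw = np.array([1.0 / freq[v] for v in y[idx]])
            try:
                model.fit(X[idx], y[idx], sample_weight=sw)
            except TypeError:
                model.fit(X[idx], y[idx])
        else:
            model.fit(X[idx], y[idx])
        learners.append(model)
    return BaggedEnsemble(learners, membership, classes, positive_class, seed)


def _vote(preds: np.ndarray, classes: np.ndarray, positive) -> object:
    """Majority vote; ties go to the positive (more severe) class."""
    vals, counts = np.unique(preds, return_counts=True)
    winners = vals[counts == counts.max()]
    if len(winners) > 1 and positive in winners:
        return positive
    return winners[0]


def oob_predict(ensemble: BaggedEnsemble, X: np.ndarray,
                return_flags: bool = False):
    """OOB majority-vote label per training subject.

    Votes come only from learners whose resample excluded the subject; a
    subject in every resample falls back to the full-ensemble vote (flagged).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    all_preds = np.stack([m.predict(X) for m in ensemble.learners], axis=1)  # (N, B)
    out = np.empty(n, dtype=all_preds.dtype)
    never_oob = np.zeros(n, dtype=bool)
    for i in range(n):
        oob = ensemble.membership[i] == 0
        votes = all_preds[i, oob] if np.any(oob) else all_preds[i]
        never_oob[i] = not np.any(oob)
        out[i] = _vote(votes, ensemble.classes, ensemble.positive_class)
    return (out, never_oob) if return_flags else out


def ensemble_predict(ensemble: BaggedEnsemble, X: np.ndarray) -> np.ndarray:
    """Full-ensemble majority vote on new data."""
    all_preds = np.stack([m.predict(np.asarray(X, dtype=float))
                          for m in ensemble.learners], axis=1)
    return np.array([_vote(all_preds[i], ensemble.classes, ensemble.positive_class)
                     for i in range(all_preds.shape[0])])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    context: str = "OOB"  # "OOB" | "test"
    trial: int = 0
    fold: int = -1


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray, positive,
                    context: str = "OOB", trial: int = 0, fold: int = -1
                    ) -> MetricsReport:
    """Accuracy/sensitivity/specificity with sensitivity on the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    neg = ~pos
    tp = float(np.sum(pos & (y_pred == positive)))
    tn = float(np.sum(neg & (y_pred != positive)))
    sens = tp / max(float(np.sum(pos)), 1.0)
    spec = tn / max(float(np.sum(neg)), 1.0)
    acc = float(np.mean(y_true == y_pred))
    return MetricsReport(acc, sens, spec, (sens + spec) / 2.0, context, trial, fold)


def oob_metrics(ensemble: BaggedEnsemble, X: np.ndarray, y: np.ndarray,
                trial: int = 0) -> MetricsReport:
    pred = oob_predict(ensemble, X)
    return compute_metrics(y, pred, ensemble.positive_class, "OOB", trial)


# ---------------------------------------------------------------------------
# trials, final selection, test evaluation
# ---------------------------------------------------------------------------


@dataclass
class TrialResult:
    trial: int
    params: dict
    ensemble: BaggedEnsemble
    oob: MetricsReport


def run_trials(factory: Callable[[dict], object], space: Sequence[Param],
               X: np.ndarray, y: np.ndarray, positive_class, n_trials: int = 5,
               budget: int = 50, B: int = 50, seed: int = 0) -> TrialResult:
    """Independent re-seeded tuning+bagging trials; the best OOB accuracy wins
    (ties to the lowest trial index)."""
    best: TrialResult | None = None
    for t in range(n_trials):
        trial_seed = seed * 1000 + t
        opt = bayes_opt(factory, space, X, y, budget=budget, seed=trial_seed)
        ens = fit_bagged(factory, opt.best_params, X, y, positive_class,
                         B=B, seed=trial_seed)
        rep = oob_metrics(ens, X, y, trial=t)
        if best is None or rep.accuracy > best.oob.accuracy:
            best = TrialResult(t, opt.best_params, ens, rep)
    assert best is not None
    return best


def select_final(results: dict[str, TrialResult]) -> tuple[str, TrialResult]:
    """Across classifier configs: argmax OOB accuracy, ties by config order."""
    best_name = max(results, key=lambda name: (results[name].oob.accuracy,
                                               -list(results).index(name)))
    return best_name, results[best_name]


def evaluate_test(factory: Callable[[dict], object], params: dict,
                  X_train: np.ndarray, y_train: np.ndarray,
                  X_test: np.ndarray, y_test: np.ndarray, positive_class,
                  n_repeats: int = 25, B: int = 50, seed: int = 0
                  ) -> tuple[list[MetricsReport], dict[str, float]]:
    """Retrain-and-evaluate with fresh seeds; per-repeat and aggregate metrics."""
    reports = []
    for r in range(n_repeats):
        ens = fit_bagged(factory, params, X_train, y_train, positive_class,
                         B=B, seed=seed * 997 + r)
        pred = ensemble_predict(ens, X_test)
        reports.append(compute_metrics(y_test, pred, positive_class, "test", trial=r))
    agg = {}
    for m in ("accuracy", "sensitivity", "specificity", "balanced_accuracy"):
        vals = np.array([getattr(rep, m) for rep in reports])
        agg[m + "_mean"] = float(vals.mean())
        agg[m + "_sd"] = float(vals.std())
    return reports, agg
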