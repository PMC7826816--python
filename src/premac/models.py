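"""Classifier training, validation schemes and importance analyses.

Seven standard classifier families are compared: random forest (RF),
support vector machine (SVM, RBF kernel), k-nearest neighbors (kNN),
decision tree (DT), discriminant analysis (DA, linear), naive Bayes
(NB) and a one-hidden-layer neural network (NN).  Two validation
schemes mirror the two deployment questions:

* individualized: stratified 5-fold cross-validation within one
  subject's data (an 80/20 holdout with its confusion matrix is
  available separately);
* group: leave-one-subject-out (LOSO) -- train on all other subjects,
  test on the held-out one.

Random-forest models additionally yield impurity-based feature
importances (summing to 1), aggregated per sensing modality, and a
window-sensitivity analysis re-labels the data at several pre-event
window lengths with 1:1 minority oversampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    StratifiedKFold,
    cross_val_predict,
    train_test_split,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import modality_map
from .labeling import LabeledDataset, assign_labels, concat_labeled, oversample_minority

ALGORITHMS = ("rf", "svm", "knn", "dt", "da", "nb", "nn")

_SCALED = {"svm", "knn", "nn", "da", "nb"}


class ModelError(ValueError):
    pass


def make_classifier(algorithm: str, seed: int = 0):
    """Default-hyperparameter classifier for one of the seven families.

    Distance/margin-based families are wrapped with standardization;
    tree ensembles run on raw features.
    """
    algorithm = algorithm.lower()
    if algorithm == "rf":
        est = RandomForestClassifier(n_estimators=100, random_state=seed,
                                     n_jobs=1)
    elif algorithm == "svm":
        est = SVC(kernel="rbf", random_state=seed)
    elif algorithm == "knn":
        est = KNeighborsClassifier(n_neighbors=5)
    elif algorithm == "dt":
        est = DecisionTreeClassifier(random_state=seed)
    elif algorithm == "da":
        est = LinearDiscriminantAnalysis()
    elif algorithm == "nb":
        est = GaussianNB()
    elif algorithm == "nn":
        est = MLPClassifier(hidden_layer_sizes=(64,), max_iter=300,
                            random_state=seed)
    else:
        raise ModelError(
            f"unknown algorithm '{algorithm}'; choose from {ALGORITHMS}")
    if algorithm in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class CVResult:
    algorithm: str
    accuracy: float
    fold_accuracies: list[float]
    confusion: np.ndarray  # rows actual [0,1], cols predicted [0,1]
    n: int

    @property
    def tn(self) -> int: return int(self.confusion[0, 0])
    @property
    def fp(self) -> int: return int(self.confusion[0, 1])
    @property
    def fn(self) -> int: return int(self.confusion[1, 0])
    @property
    def tp(self) -> int: return int(self.confusion[1, 1])

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm, "accuracy": self.accuracy,
            "fold_accuracies": self.fold_accuracies,
            "confusion": {"tn": self.tn, "fp": self.fp,
                          "fn": self.fn, "tp": self.tp},
            "n": self.n,
        }


def crossval_individual(
    d: LabeledDataset, algorithm: str = "rf", k: int = 5, seed: int = 0
) -> CVResult:
    """Stratified k-fold accuracy within one subject, plus the pooled
    out-of-fold confusion matrix."""
    _require_both_classes(d)
    clf = make_classifier(algorithm, seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X, y = d.X, d.y
    y_hat = cross_val_predict(clf, X, y, cv=cv, n_jobs=1)
    folds = []
    for _, test_idx in cv.split(X, y):
        folds.append(float(np.mean(y_hat[test_idx] == y[test_idx])))
    return CVResult(
        algorithm=algorithm,
        accuracy=float(np.mean(folds)),
        fold_accuracies=folds,
        confusion=confusion_matrix(y, y_hat, labels=[0, 1]),
        n=d.n,
    )


def holdout_individual(
    d: LabeledDataset, algorithm: str = "rf", test_size: float = 0.2,
    seed: int = 0,
) -> CVResult:
    """Single stratified 80/20 holdout with its confusion matrix."""
    _require_both_classes(d)
    X_tr, X_te, y_tr, y_te = train_test_split(
        d.X, d.y, test_size=test_size, random_state=seed, stratify=d.y)
    clf = make_classifier(algorithm, seed)
    clf.fit(X_tr, y_tr)
    y_hat = clf.predict(X_te)
    acc = float(np.mean(y_hat == y_te))
    return CVResult(algorithm, acc, [acc],
                    confusion_matrix(y_te, y_hat, labels=[0, 1]), len(y_te))


@dataclass
class LosoResult:
    algorithm: str
    per_subject: dict[str, float]
    flagged: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    def as_dict(self) -> dict:
        return {"algorithm": self.algorithm,
                "per_subject": self.per_subject,
                "mean_accuracy": self.mean_accuracy,
                "flagged": self.flagged}


def loso_group(
    datasets: list[LabeledDataset], algorithm: str = "rf", seed: int = 0
) -> LosoResult:
    """Leave-one-subject-out validation across a cohort.

    For each subject a model is trained on the pooled data of all other
    subjects and tested on the held-out subject.  Single-class subjects
    are flagged and skipped as test folds.
    """
    if len(datasets) < 2:
        raise ModelError("LOSO requires at least 2 subjects")
    ids = [d.subject_id or f"subject_{i + 1:02d}"
           for i, d in enumerate(datasets)]
    per_subject: dict[str, float] = {}
    flagged: list[str] = []
    for i, held_out in enumerate(datasets):
        if len(np.unique(held_out.y)) < 2:
            flagged.append(ids[i])
            continue
        X_tr = np.vstack([d.X for j, d in enumerate(datasets) if j != i])
        y_tr = np.concatenate([d.y for j, d in enumerate(datasets) if j != i])
        clf = make_classifier(algorithm, seed)
        clf.fit(X_tr, y_tr)
        per_subject[ids[i]] = float(np.mean(clf.predict(held_out.X)
                                            == held_out.y))
    return LosoResult(algorithm, per_subject, flagged)


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------


def fit_rf(d: LabeledDataset, seed: int = 0) -> RandomForestClassifier:
    clf = make_classifier("rf", seed)
    clf.fit(d.X, d.y)
    return clf


def feature_importance(
    model: RandomForestClassifier,
    columns: list[str],
    grouping: dict[str, str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Impurity-based per-feature importances and per-modality sums.

    Importances are the mean over trees of the total impurity decrease
    contributed by each feature, weighted by the probability of reaching
    the node; they are non-negative and sum to 1.
    """
    if not isinstance(model, RandomForestClassifier):
        raise ModelError("impurity importances require a fitted random forest")
    imp = pd.Series(model.feature_importances_, index=columns)
    grouping = grouping or modality_map(columns)
    by_modality = imp.groupby(grouping).sum().sort_values(ascending=False)
    return imp.sort_values(ascending=False), by_modality


# ---------------------------------------------------------------------------
# Window-sensitivity analysis
# ---------------------------------------------------------------------------


def window_sensitivity(
    sessions: list[tuple],
    algorithm: str = "rf",
    windows: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0),
    seed: int = 0,
    subject_id: str = "",
) -> dict[float, float]:
    """Accuracy as a function of the pre-event window length.

    ``sessions`` is a list of ``(FeatureMatrix, EventLog)`` pairs for
    one subject.  For each window the data are re-labeled, the minority
    class oversampled to a 1:1 ratio, and the 5-fold accuracy computed
    under the same algorithm and seed protocol.
    """
    out: dict[float, float] = {}
    for w in windows:
        if w <= 0:
            raise ModelError(f"window must be > 0 s, got {w}")
        parts = [assign_labels(fm, log, w, subject_id) for fm, log in sessions]
        d = concat_labeled(parts, subject_id)
        d = oversample_minority(d, seed=seed)
        out[w] = crossval_individual(d, algorithm, k=5, seed=seed).accuracy
    return out


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Cohort-level results bundle, JSON-serializable."""

    individualized: dict[str, dict[str, CVResult]] = field(default_factory=dict)
    group: dict[str, LosoResult] = field(default_factory=dict)
    feature_importances: dict[str, float] = field(default_factory=dict)
    modality_importances: dict[str, float] = field(default_factory=dict)
    window_accuracies: dict[str, dict[float, float]] = field(default_factory=dict)

    def individualized_mean(self, algorithm: str) -> float:
        res = self.individualized[algorithm]
        return float(np.mean([r.accuracy for r in res.values()]))

    def as_dict(self) -> dict:
        return {
            "individualized": {
                alg: {sid: r.as_dict() for sid, r in res.items()}
                for alg, res in self.individualized.items()
            },
            "individualized_mean": {
                alg: self.individualized_mean(alg)
                for alg in self.individualized
            },
            "group": {alg: r.as_dict() for alg, r in self.group.items()},
            "feature_importances": self.feature_importances,
            "modality_importances": self.modality_importances,
            "window_accuracies": {
                k: {str(w): a for w, a in v.items()}
                for k, v in self.window_accuracies.items()
            },
        }


def evaluate_cohort(
    datasets: list[LabeledDataset],
    algorithms: tuple[str, ...] = ("rf",),
    mode: str = "individual",
    seed: int = 0,
) -> EvaluationReport:
    """Run the chosen validation scheme(s) over a cohort of labeled sets."""
    report = EvaluationReport()
    for alg in algorithms:
        if mode in ("individual", "both"):
            report.individualized[alg] = {
                (d.subject_id or f"subject_{i + 1:02d}"):
                    crossval_individual(d, alg, seed=seed)
                for i, d in enumerate(datasets)
            }
        if mode in ("group", "both") and len(datasets) >= 2:
            report.group[alg] = loso_group(datasets, alg, seed=seed)
    if datasets and "rf" in algorithms:
        pooled = datasets[0]
        rf = fit_rf(pooled, seed=seed)
        per_feat, per_mod = feature_importance(rf, pooled.features.columns)
        report.feature_importances = per_feat.to_dict()
        report.modality_importances = per_mod.to_dict()
    return report


def _require_both_classes(d: LabeledDataset) -> None:
    if len(np.unique(d.y)) < 2:
        raise ModelError("dataset contains a single class")


def label_permutation_control(
    d: LabeledDataset, algorithm: str = "rf", seed: int = 0
) -> float:
    """Chance-level control: accuracy after randomly permuting labels."""
    rng = np.random.default_rng(seed)
    shuffled = dataclasses.replace(d, labels=rng.permutation(d.labels))
    return crossval_individual(shuffled, algorithm, seed=seed).accuracy
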