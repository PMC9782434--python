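"""Classifier benchmark: 13 algorithm variants x 4 classification experiments.

The benchmark trains point-and-click style preset classifiers — three
Decision Trees (fine/medium/coarse), six k-Nearest-Neighbour variants
(fine/medium/coarse/cosine/cubic/weighted), three polynomial-kernel Support
Vector Machines (linear/quadratic/cubic) and one shallow Artificial Neural
Network — on the 72-feature table, for four two-class experiments:

* ``PDvsHC``  — all PD rows (ON and OFF) vs healthy controls; positive = PD
* ``OFFvsHC`` — medication-OFF rows vs controls; positive = OFF
* ``ONvsHC``  — medication-ON rows vs controls; positive = ON
* ``OFFvsON`` — within-patient medication contrast; positive = ON

Cross-validation is subject-grouped (all rows of a subject share a fold, so
a patient's ON row can never train the prediction of their own OFF row) and
stratified by class as far as the grouping allows.  Out-of-fold predictions
are pooled into a single confusion matrix per (experiment, classifier);
positive-class scores are pooled alongside for ROC analysis.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

log = logging.getLogger(__name__)

__all__ = [
    "Family",
    "ClassifierSpec",
    "ExperimentDef",
    "ConfusionMatrix",
    "CVScheme",
    "BenchResult",
    "EXPERIMENTS",
    "default_classifier_specs",
    "enumerate_bench",
    "make_estimator",
    "cross_validate",
]


class Family(str, enum.Enum):
    DT = "DT"
    KNN = "KNN"
    SVM = "SVM"
    ANN = "ANN"


@dataclass(frozen=True)
class ClassifierSpec:
    """One preset classifier variant with explicit hyperparameters."""

    family: Family
    variant: str
    params: tuple[tuple[str, object], ...] = ()
    rng_seed: int = 0

    @property
    def name(self) -> str:
        return f"{self.family.value}_{self.variant}"

    def param_dict(self) -> dict:
        return dict(self.params)


def _spec(family: Family, variant: str, **params) -> ClassifierSpec:
    return ClassifierSpec(family=family, variant=variant,
                          params=tuple(sorted(params.items())))


def default_classifier_specs(rng_seed: int = 0) -> list[ClassifierSpec]:
    """The 13 preset variants benchmarked by the pipeline."""
    specs = [
        _spec(Family.DT, "fine", max_splits=100),
        _spec(Family.DT, "medium", max_splits=20),
        _spec(Family.DT, "coarse", max_splits=4),
        _spec(Family.KNN, "fine", n_neighbors=1, metric="euclidean"),
        _spec(Family.KNN, "medium", n_neighbors=10, metric="euclidean"),
        _spec(Family.KNN, "coarse", n_neighbors=100, metric="euclidean"),
        _spec(Family.KNN, "cosine", n_neighbors=10, metric="cosine"),
        _spec(Family.KNN, "cubic", n_neighbors=10, metric="minkowski3"),
        _spec(Family.KNN, "weighted", n_neighbors=10, metric="euclidean",
              weights="squared_inverse"),
        _spec(Family.SVM, "linear", degree=1),
        _spec(Family.SVM, "quadratic", degree=2),
        _spec(Family.SVM, "cubic", degree=3),
        _spec(Family.ANN, "shallow", hidden_units=10),
    ]
    return [ClassifierSpec(s.family, s.variant, s.params, rng_seed)
            for s in specs]


@dataclass(frozen=True)
class ExperimentDef:
    """A two-class experiment over the feature table."""

    name: str
    positive_class: str
    negative_class: str

    def select(self, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
        """Rows, labels and subject groups for this experiment."""
        lab = _row_class(table, self)
        mask = lab.notna()
        sub = table.loc[mask]
        return sub, lab[mask], sub["subject_id"]


def _row_class(table: pd.DataFrame, exp: ExperimentDef) -> pd.Series:
    """Class label of each row under *exp* (NaN = row excluded)."""
    out = pd.Series(pd.NA, index=table.index, dtype=object)
    if exp.name == "PDvsHC":
        out[table["group"] == "PD"] = "PD"
        out[table["group"] == "HC"] = "HC"
    elif exp.name in ("OFFvsHC", "ONvsHC"):
        state = exp.name[:-4]  # OFF or ON
        out[table["state"] == state] = state
        out[table["group"] == "HC"] = "HC"
    elif exp.name == "OFFvsON":
        out[table["state"] == "OFF"] = "OFF"
        out[table["state"] == "ON"] = "ON"
    else:
        raise ValueError(f"unknown experiment {exp.name!r}")
    return out


EXPERIMENTS: tuple[ExperimentDef, ...] = (
    ExperimentDef("PDvsHC", positive_class="PD", negative_class="HC"),
    ExperimentDef("OFFvsHC", positive_class="OFF", negative_class="HC"),
    ExperimentDef("ONvsHC", positive_class="ON", negative_class="HC"),
    ExperimentDef("OFFvsON", positive_class="ON", negative_class="OFF"),
)


def enumerate_bench(
    experiments: tuple[ExperimentDef, ...] = EXPERIMENTS,
    specs: list[ClassifierSpec] | None = None,
) -> list[tuple[ExperimentDef, ClassifierSpec]]:
    """Deterministic cross product of experiments and classifier variants."""
    if specs is None:
        specs = default_classifier_specs()
    return [(exp, spec) for exp in experiments for spec in specs]


@dataclass
class ConfusionMatrix:
    """Pooled binary confusion counts with an explicit positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "positive_class": self.positive_class}

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive_class: str
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=object)
        y_pred = np.asarray(y_pred, dtype=object)
        pos = y_true == positive_class
        hit = y_pred == y_true
        return cls(tp=int(np.sum(pos & hit)),
                   fn=int(np.sum(pos & ~hit)),
                   tn=int(np.sum(~pos & hit)),
                   fp=int(np.sum(~pos & ~hit)),
                   positive_class=positive_class)


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: stratified subject-grouped k-fold or LOSO."""

    kind: str = "kfold"   # "kfold" | "loso"
    k: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("kfold", "loso"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class BenchResult:
    """Outcome of one (experiment, classifier) cross-validation."""

    experiment: str
    classifier: str
    confusion: ConfusionMatrix
    scores: pd.DataFrame        # columns: subject_id, label, score
    scheme: CVScheme
    n_folds: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "experiment": self.experiment,
            "classifier": self.classifier,
            "confusion": self.confusion.to_dict(),
            "scheme": {"kind": self.scheme.kind, "k": self.scheme.k,
                       "rng_seed": self.scheme.rng_seed},
            "n_folds": self.n_folds,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# Estimator construction


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        w = 1.0 / (dist ** 2)
    # exact-match neighbours get all the weight
    inf = np.isinf(w)
    if inf.any():
        w[inf.any(axis=1)] = inf[inf.any(axis=1)].astype(float)
    return w


def make_estimator(spec: ClassifierSpec, n_train: int | None = None):
    """Instantiate the scikit-learn estimator for *spec*.

    Distance- and gradient-based families (KNN, SVM, ANN) are wrapped in a
    standardization pipeline so scaling is always fitted on training folds
    only.  *n_train* caps KNN neighbour counts at the training-set size.
    """
    p = spec.param_dict()
    if spec.family is Family.DT:
        est = DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=int(p["max_splits"]) + 1,
            random_state=spec.rng_seed,
        )
        return est
    if spec.family is Family.KNN:
        k = int(p["n_neighbors"])
        if n_train is not None:
            k = min(k, n_train)
        metric = p["metric"]
        kw: dict = {"n_neighbors": k}
        if metric == "minkowski3":
            kw.update(metric="minkowski", p=3)
        else:
            kw.update(metric=metric)
        if p.get("weights") == "squared_inverse":
            kw.update(weights=_squared_inverse)
        est = KNeighborsClassifier(**kw)
    elif spec.family is Family.SVM:
        est = SVC(kernel="poly", degree=int(p["degree"]), coef0=1.0,
                  gamma="scale", C=1.0, random_state=spec.rng_seed)
    elif spec.family is Family.ANN:
        # the inner validation split needs enough rows to hold both classes
        use_es = n_train is None or int(0.15 * n_train) >= 4
        est = MLPClassifier(
            hidden_layer_sizes=(int(p["hidden_units"]),),
            activation="logistic", solver="adam", max_iter=800,
            early_stopping=use_es, validation_fraction=0.15,
            n_iter_no_change=25, random_state=spec.rng_seed,
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown family {spec.family}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def _positive_score(model, X: np.ndarray, positive_class: str) -> np.ndarray:
    """Pooled ROC score of the positive class for any supported estimator."""
    clf = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    classes = list(clf.classes_)
    if hasattr(clf, "decision_function") and len(classes) == 2:
        s = model.decision_function(X)
        return s if classes[1] == positive_class else -s
    proba = model.predict_proba(X)
    return proba[:, classes.index(positive_class)]


# --------------------------------------------------------------------------
# Cross-validation


def _grouped_stratified_folds(
    subjects: pd.Series, labels: pd.Series, k: int, rng_seed: int
) -> list[np.ndarray]:
    """Assign subjects to folds, stratifying by the subject's class.

    Subjects whose rows span both classes (the within-patient experiment)
    form their own stratum and are spread round-robin.  Returns per-fold
    boolean row masks.
    """
    subjects = subjects.reset_index(drop=True)
    labels = labels.reset_index(drop=True)
    rng = np.random.default_rng(rng_seed)

    subj_class: dict[str, str] = {}
    for s in subjects.unique():
        cls = labels[subjects == s].unique()
        subj_class[s] = cls[0] if len(cls) == 1 else "__mixed__"

    n_units = len(subj_class)
    if k > n_units:
        log.warning("k=%d exceeds the %d subject groups; reducing k to %d",
                    k, n_units, n_units)
        k = n_units

    strata: dict[str, list[str]] = {}
    for s, c in subj_class.items():
        strata.setdefault(c, []).append(s)

    fold_of: dict[str, int] = {}
    next_fold = 0
    for cls in sorted(strata):
        members = sorted(strata[cls])
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            fold_of[members[idx]] = (next_fold + j) % k
        next_fold = (next_fold + len(members)) % k

    masks = []
    fold_ids = subjects.map(fold_of).to_numpy()
    for f in range(k):
        mask = fold_ids == f
        if mask.any():
            masks.append(mask)
    return masks


def cross_validate(
    spec: ClassifierSpec,
    experiment: ExperimentDef,
    table: pd.DataFrame,
    scheme: CVScheme | None = None,
) -> BenchResult:
    """Cross-validate one classifier on one experiment, pooling predictions.

    The default scheme is subject-grouped stratified 50-fold for DT/KNN/SVM
    and leave-one-subject-out for the ANN.
    """
    if scheme is None:
        scheme = (CVScheme(kind="loso") if spec.family is Family.ANN
                  else CVScheme(kind="kfold", k=50))

    sub, labels, subjects = experiment.select(table)
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError(
            f"experiment {experiment.name} has a single class: {classes}")
    counts = labels.value_counts()
    if counts.min() < 2:
        raise ValueError(
            f"experiment {experiment.name} needs >= 2 samples per class, "
            f"got {counts.to_dict()}")

    X = sub[list(FEATURE_NAMES)].to_numpy(float)
    y = labels.to_numpy(object)

    if scheme.kind == "loso":
        uniq = sorted(subjects.unique())
        masks = [subjects.to_numpy() == s for s in uniq]
    else:
        masks = _grouped_stratified_folds(subjects, labels, scheme.k,
                                          scheme.rng_seed)

    y_pred = np.empty_like(y)
    score = np.empty(len(y), dtype=float)
    n_folds = 0
    for test_mask in masks:
        train_mask = ~test_mask
        train_y = y[train_mask]
        if len(np.unique(train_y)) < 2:
            # degenerate fold split; predict the only training class
            y_pred[test_mask] = train_y[0]
            score[test_mask] = 0.0
            n_folds += 1
            continue
        model = make_estimator(spec, n_train=int(train_mask.sum()))
        model = clone(model)
        model.fit(X[train_mask], train_y)
        y_pred[test_mask] = model.predict(X[test_mask])
        score[test_mask] = _positive_score(
            model, X[test_mask], experiment.positive_class)
        n_folds += 1

    cm = ConfusionMatrix.from_predictions(
        y, y_pred, experiment.positive_class)
    scores = pd.DataFrame({
        "subject_id": subjects.to_numpy(),
        "label": y,
        "score": score,
    })
    return BenchResult(experiment=experiment.name, classifier=spec.name,
                       confusion=cm, scores=scores, scheme=scheme,
                       n_folds=n_folds)
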