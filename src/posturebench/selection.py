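"""Threshold gates, goodness index and best-classifier selection.

Candidate classifiers are screened by three threshold criteria applied in
order — accuracy (ACC), recall (TPR), precision (PPV), each at 80% — and
the survivors ranked by the goodness index

    G = sqrt((1 - TPR)^2 + (1 - TNR)^2)     (rates as fractions)

the Euclidean distance in ROC space from the perfect-classifier corner
(FPR 0, TPR 1).  G ranges from 0 (perfect) to sqrt(2) (always wrong); a
chance-level classifier (TPR = TNR = 50%) sits at G ~= 0.70.  Classifiers
with G <= 0.25 are labelled *optimum*, those in (0.25, 0.70] *good*, and
those beyond 0.70 *bad*.  A combination that fails a gate is not evaluated
further (exported as "/" in the report).  The module also computes pooled
out-of-fold ROC/AUC.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .bench import BenchResult, ConfusionMatrix

__all__ = [
    "Category",
    "MetricSet",
    "GateOutcome",
    "SelectionRow",
    "SelectionReport",
    "compute_metrics",
    "goodness_index",
    "categorize",
    "apply_gates",
    "evaluate_bench",
    "select_best",
    "roc_auc",
    "find_consistent_matrices",
]

THRESHOLD_PCT = 80.0


class Category(str, enum.Enum):
    OPTIMUM = "optimum"
    GOOD = "good"
    RANDOM = "random"
    BAD = "bad"
    NOT_EVALUATED = "not_evaluated"


@dataclass
class MetricSet:
    """Percent-scale classification metrics plus the goodness index."""

    acc: float
    tpr: float
    tnr: float
    ppv: float | None          # None when TP + FP = 0 (undefined)
    goodness: float
    auc: float | None = None


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """ACC/TPR/TNR/PPV (percent) and goodness index of a confusion matrix."""
    if cm.p == 0 or cm.n == 0:
        raise ValueError(
            "metrics require at least one actual positive and one actual "
            f"negative (P={cm.p}, N={cm.n})")
    acc = 100.0 * (cm.tp + cm.tn) / (cm.p + cm.n)
    tpr = 100.0 * cm.tp / (cm.tp + cm.fn)
    tnr = 100.0 * cm.tn / (cm.tn + cm.fp)
    ppv = 100.0 * cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) > 0 else None
    return MetricSet(acc=acc, tpr=tpr, tnr=tnr, ppv=ppv,
                     goodness=goodness_index(tpr, tnr))


def goodness_index(tpr_pct: float, tnr_pct: float) -> float:
    """Distance in ROC space from the perfect-classifier corner.

    Inputs are percentages in [0, 100]; the result lies in [0, sqrt(2)]
    and is 0 exactly when both rates are 100%.
    """
    for name, v in (("TPR", tpr_pct), ("TNR", tnr_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    return math.hypot(1.0 - tpr_pct / 100.0, 1.0 - tnr_pct / 100.0)


def categorize(goodness: float) -> Category:
    """Goodness-index category: optimum <= 0.25 < good <= 0.70 < bad.

    The chance-level reference value 0.70 itself falls in the *good*
    interval under the interval reading; it is flagged separately in the
    report export.
    """
    if not 0.0 <= goodness <= math.sqrt(2.0) + 1e-12:
        raise ValueError(f"goodness index {goodness} outside [0, sqrt(2)]")
    if goodness <= 0.25:
        return Category.OPTIMUM
    if goodness <= 0.70:
        return Category.GOOD
    return Category.BAD


@dataclass
class GateOutcome:
    """Ordered 80% threshold gates; a failed gate blocks the later ones."""

    passed_acc: bool
    passed_recall: bool | None    # None = blocked by an earlier gate
    passed_precision: bool | None

    @property
    def all_passed(self) -> bool:
        return bool(self.passed_acc and self.passed_recall
                    and self.passed_precision)


def apply_gates(metrics: MetricSet,
                threshold_pct: float = THRESHOLD_PCT) -> GateOutcome:
    """Evaluate the ACC -> TPR -> PPV gates on one-decimal rounded values."""
    def ok(value: float | None) -> bool:
        return value is not None and round(value, 1) >= threshold_pct

    if not ok(metrics.acc):
        return GateOutcome(False, None, None)
    if not ok(metrics.tpr):
        return GateOutcome(True, False, None)
    return GateOutcome(True, True, ok(metrics.ppv))


@dataclass
class SelectionRow:
    experiment: str
    classifier: str
    metrics: MetricSet
    gates: GateOutcome
    category: Category


@dataclass
class SelectionReport:
    rows: list[SelectionRow]
    best: dict[str, str | None]    # experiment -> classifier name or None
    threshold_pct: float = THRESHOLD_PCT

    def to_frame(self) -> pd.DataFrame:
        """Tabular export; gate-blocked cells are rendered as "/"."""
        recs = []
        for r in self.rows:
            m, g = r.metrics, r.gates
            rec = {
                "experiment": r.experiment,
                "classifier": r.classifier,
                "ACC": f"{m.acc:.1f}",
                "TPR": f"{m.tpr:.1f}" if g.passed_acc else "/",
                "PPV": ("/" if not (g.passed_acc and g.passed_recall)
                        else ("undef" if m.ppv is None else f"{m.ppv:.1f}")),
                "G": f"{m.goodness:.2f}" if g.all_passed else "/",
                "category": r.category.value,
                "AUC": "" if m.auc is None else f"{m.auc:.2f}",
                "best": "*" if self.best.get(r.experiment) == r.classifier
                        else "",
            }
            recs.append(rec)
        return pd.DataFrame(recs)


def evaluate_bench(results: list[BenchResult],
                   threshold_pct: float = THRESHOLD_PCT) -> SelectionReport:
    """Run the full gate + goodness selection flow over benchmark results."""
    rows: list[SelectionRow] = []
    for res in results:
        m = compute_metrics(res.confusion)
        try:
            m.auc = roc_auc(res.scores["score"],
                            res.scores["label"],
                            res.confusion.positive_class)
        except ValueError:
            m.auc = None
        gates = apply_gates(m, threshold_pct)
        cat = categorize(m.goodness) if gates.all_passed \
            else Category.NOT_EVALUATED
        rows.append(SelectionRow(res.experiment, res.classifier, m, gates,
                                 cat))
    return SelectionReport(rows=rows, best=select_best(rows),
                           threshold_pct=threshold_pct)


def select_best(rows: list[SelectionRow]) -> dict[str, str | None]:
    """Per experiment, the gate-passing classifier with the lowest goodness.

    Ties break toward higher accuracy, then lexicographic classifier name;
    experiments with no gate-passing combination map to ``None``.
    """
    best: dict[str, str | None] = {}
    for r in rows:
        best.setdefault(r.experiment, None)
    ranked: dict[str, tuple] = {}
    for r in rows:
        if not r.gates.all_passed:
            continue
        key = (r.metrics.goodness, -r.metrics.acc, r.classifier)
        if r.experiment not in ranked or key < ranked[r.experiment][0]:
            ranked[r.experiment] = (key, r.classifier)
    for exp, (_, name) in ranked.items():
        best[exp] = name
    return best


def roc_auc(scores, labels, positive_class: str) -> float:
    """Area under the empirical ROC of pooled out-of-fold scores.

    Trapezoidal integration of the ROC curve; with ties this equals the
    Mann-Whitney rank statistic normalized by P*N.
    """
    labels = np.asarray(labels, dtype=object)
    y = (labels == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# --------------------------------------------------------------------------
# Consistency search against printed metric quadruples


def find_consistent_matrices(
    acc_pct: float,
    tpr_pct: float,
    ppv_pct: float,
    goodness: float,
    max_total: int = 200,
    pct_decimals: int = 1,
    g_tol: float = 0.005,
) -> list[ConfusionMatrix]:
    """Integer confusion matrices reproducing a printed metric quadruple.

    Searches all matrices with total count <= *max_total* whose ACC, TPR and
    PPV round (to *pct_decimals*) to the given percentages and whose
    goodness index lies within *g_tol* of the given value (the default
    corresponds to a two-decimal print).  Used to check that the metric
    implementation is consistent with published results when the underlying
    data are unavailable; a two-decimal index published from a truncated
    rather than rounded value needs ``g_tol=0.01``.
    """
    out: list[ConfusionMatrix] = []
    half_pct = 0.5 * 10.0 ** (-pct_decimals)
    for p in range(1, max_total):
        tp_lo = math.ceil(p * (tpr_pct - half_pct) / 100.0)
        tp_hi = math.floor(p * (tpr_pct + half_pct) / 100.0)
        for tp in range(max(tp_lo, 0), min(tp_hi, p) + 1):
            if round(100.0 * tp / p, pct_decimals) != round(tpr_pct,
                                                            pct_decimals):
                continue
            if tp > 0:
                fp_lo = math.ceil(tp * (100.0 / (ppv_pct + half_pct) - 1.0))
                fp_hi = math.floor(tp * (100.0 / (ppv_pct - half_pct) - 1.0))
            else:
                fp_lo, fp_hi = 0, max_total
            for fp in range(max(fp_lo, 0), fp_hi + 1):
                if tp + fp > 0 and round(100.0 * tp / (tp + fp),
                                         pct_decimals) != round(
                                             ppv_pct, pct_decimals):
                    continue
                for n in range(max(fp, 1), max_total - p + 1):
                    cm = ConfusionMatrix(tp=tp, fp=fp, tn=n - fp,
                                         fn=p - tp, positive_class="pos")
                    m = compute_metrics(cm)
                    if round(m.acc, pct_decimals) != round(acc_pct,
                                                           pct_decimals):
                        continue
                    if abs(m.goodness - goodness) > g_tol:
                        continue
                    out.append(cm)
    return out
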