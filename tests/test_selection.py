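"""Metric gates, goodness index, categories, selection flow and ROC/AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturebench.bench import ConfusionMatrix
from posturebench.selection import (
    Category,
    GateOutcome,
    MetricSet,
    SelectionRow,
    apply_gates,
    categorize,
    compute_metrics,
    find_consistent_matrices,
    goodness_index,
    roc_auc,
    select_best,
)

cm_strategy = st.builds(
    ConfusionMatrix,
    tp=st.integers(0, 100), fp=st.integers(0, 100),
    tn=st.integers(0, 100), fn=st.integers(0, 100),
    positive_class=st.just("pos"),
).filter(lambda c: c.p > 0 and c.n > 0)


class TestComputeMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionMatrix(tp=9, fn=1, tn=8, fp=2,
                                            positive_class="pos"))
        assert m.acc == pytest.approx(85.0)
        assert m.tpr == pytest.approx(90.0)
        assert m.tnr == pytest.approx(80.0)
        assert m.ppv == pytest.approx(100 * 9 / 11)

    def test_perfect_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=5, fn=0, tn=7, fp=0,
                                            positive_class="pos"))
        assert (m.acc, m.tpr, m.tnr, m.ppv) == (100.0, 100.0, 100.0, 100.0)
        assert m.goodness == 0.0

    def test_undefined_precision_flagged(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=5,
                                            positive_class="pos"))
        assert m.ppv is None

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_metrics(ConfusionMatrix(tp=5, fn=0, tn=0, fp=0,
                                            positive_class="pos"))

    @settings(deadline=None, max_examples=200)
    @given(cm=cm_strategy)
    def test_against_direct_count_oracle(self, cm):
        """Metrics agree with counting over an explicit label/pred list."""
        y_true = ["pos"] * (cm.tp + cm.fn) + ["neg"] * (cm.tn + cm.fp)
        y_pred = (["pos"] * cm.tp + ["neg"] * cm.fn
                  + ["neg"] * cm.tn + ["pos"] * cm.fp)
        m = compute_metrics(cm)
        correct = sum(a == b for a, b in zip(y_true, y_pred))
        assert m.acc == pytest.approx(100 * correct / len(y_true))
        pos_hits = sum(a == b == "pos" for a, b in zip(y_true, y_pred))
        assert m.tpr == pytest.approx(100 * pos_hits / y_true.count("pos"))
        pred_pos = y_pred.count("pos")
        if pred_pos:
            assert m.ppv == pytest.approx(100 * pos_hits / pred_pos)

    @settings(deadline=None, max_examples=200)
    @given(cm=cm_strategy)
    def test_accuracy_identity(self, cm):
        """ACC == (TPR*P + TNR*N) / (P+N) for every confusion matrix."""
        m = compute_metrics(cm)
        assert m.acc == pytest.approx(
            (m.tpr * cm.p + m.tnr * cm.n) / (cm.p + cm.n))


class TestGoodnessIndex:
    def test_endpoints_and_chance(self):
        assert goodness_index(100, 100) == 0.0
        assert goodness_index(0, 0) == pytest.approx(math.sqrt(2))
        assert goodness_index(50, 50) == pytest.approx(math.sqrt(0.5))
        # the chance-level reference the selection flow quotes as 0.70
        assert goodness_index(50, 50) == pytest.approx(0.70, abs=0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            goodness_index(-1, 50)
        with pytest.raises(ValueError):
            goodness_index(50, 101)

    @settings(deadline=None, max_examples=200)
    @given(tpr=st.floats(0, 100), tnr=st.floats(0, 100),
           d=st.floats(0.01, 50))
    def test_monotone_in_both_rates(self, tpr, tnr, d):
        g = goodness_index(tpr, tnr)
        assert goodness_index(min(tpr + d, 100), tnr) <= g + 1e-12
        assert goodness_index(tpr, min(tnr + d, 100)) <= g + 1e-12


class TestCategorize:
    @pytest.mark.parametrize("g,expected", [
        (0.14, Category.OPTIMUM),
        (0.25, Category.OPTIMUM),     # boundary inclusive
        (0.2500001, Category.GOOD),
        (0.70, Category.GOOD),
        (1.0, Category.BAD),
        (math.sqrt(2), Category.BAD),
    ])
    def test_boundaries(self, g, expected):
        assert categorize(g) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(-0.1)
        with pytest.raises(ValueError):
            categorize(1.5)


class TestGates:
    def _metrics(self, acc, tpr, ppv):
        return MetricSet(acc=acc, tpr=tpr, tnr=90.0, ppv=ppv,
                         goodness=goodness_index(tpr, 90.0))

    def test_failed_accuracy_blocks_later_gates(self):
        g = apply_gates(self._metrics(79.9, 95.0, 95.0))
        assert (g.passed_acc, g.passed_recall, g.passed_precision) \
            == (False, None, None)

    def test_failed_recall_blocks_precision(self):
        g = apply_gates(self._metrics(90.0, 79.9, 95.0))
        assert (g.passed_acc, g.passed_recall, g.passed_precision) \
            == (True, False, None)

    def test_threshold_is_inclusive_on_rounded_values(self):
        g = apply_gates(self._metrics(79.96, 80.0, 80.0))
        assert g.all_passed  # 79.96 rounds to 80.0

    def test_undefined_precision_fails_gate(self):
        m = MetricSet(acc=90.0, tpr=90.0, tnr=90.0, ppv=None, goodness=0.1)
        assert apply_gates(m).passed_precision is False


class TestSelectBest:
    def _row(self, exp, name, g, acc=90.0, passed=True):
        gates = GateOutcome(passed, passed, passed) if passed else \
            GateOutcome(False, None, None)
        m = MetricSet(acc=acc, tpr=90.0, tnr=90.0, ppv=90.0, goodness=g)
        cat = categorize(g) if passed else Category.NOT_EVALUATED
        return SelectionRow(exp, name, m, gates, cat)

    def test_lowest_goodness_wins(self):
        rows = [self._row("E", "A", 0.20), self._row("E", "B", 0.14)]
        assert select_best(rows) == {"E": "B"}

    def test_tie_broken_by_accuracy_then_name(self):
        rows = [self._row("E", "B", 0.2, acc=85.0),
                self._row("E", "A", 0.2, acc=95.0)]
        assert select_best(rows) == {"E": "A"}
        rows = [self._row("E", "B", 0.2), self._row("E", "A", 0.2)]
        assert select_best(rows) == {"E": "A"}

    def test_no_passers_reports_none(self):
        rows = [self._row("E", "A", 0.2, passed=False)]
        assert select_best(rows) == {"E": None}

    def test_single_passer_selected_regardless_of_goodness(self):
        rows = [self._row("E", "A", 1.0)]
        assert select_best(rows) == {"E": "A"}


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = ["n", "n", "p", "p"]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels, "p") == 1.0

    def test_reversed_ranking(self):
        labels = ["n", "n", "p", "p"]
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels, "p") == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc([0.1, 0.2], ["p", "p"], "p")

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        labels = np.where(rng.random(n) < 0.5, "p", "n")
        auc = roc_auc(rng.random(n), labels, "p")
        assert auc == pytest.approx(0.5, abs=0.03)

    @settings(deadline=None, max_examples=50)
    @given(data=st.data())
    def test_equals_mann_whitney_pair_counting(self, data):
        """AUC == P(score_pos > score_neg) + 0.5*P(tie), by brute force."""
        n_pos = data.draw(st.integers(1, 8))
        n_neg = data.draw(st.integers(1, 8))
        scores = data.draw(st.lists(
            st.integers(0, 5), min_size=n_pos + n_neg,
            max_size=n_pos + n_neg))
        labels = ["p"] * n_pos + ["n"] * n_neg
        pos = scores[:n_pos]
        neg = scores[n_pos:]
        wins = sum(sp > sn for sp in pos for sn in neg)
        ties = sum(sp == sn for sp in pos for sn in neg)
        expected = (wins + 0.5 * ties) / (n_pos * n_neg)
        assert roc_auc(scores, labels, "p") == pytest.approx(expected)


class TestConsistencySearch:
    def test_recovers_a_planted_matrix(self):
        cm = ConfusionMatrix(tp=45, fn=5, tn=40, fp=10,
                             positive_class="pos")
        m = compute_metrics(cm)
        found = find_consistent_matrices(m.acc, m.tpr, m.ppv, m.goodness,
                                         max_total=120)
        assert any(f.tp == 45 and f.fp == 10 and f.tn == 40 and f.fn == 5
                   for f in found)

    def test_impossible_quadruple_finds_nothing(self):
        # TPR 100 with ACC 10 and PPV 100 cannot coexist in <= 60 samples
        found = find_consistent_matrices(10.0, 100.0, 100.0, 0.0,
                                         max_total=60)
        assert found == []
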