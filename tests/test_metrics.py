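"""Confusion matrix, CCR, minimum sensitivity, AUC/ROC and PR metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcvnet.metrics import (
    ConfusionMatrix,
    auc,
    ccr,
    compute_report,
    confusion_matrix,
    min_sensitivity,
    pr_points_and_auc,
    roc_points,
    sensitivities,
)

# Confusion matrices of the reference best RBF model, order (treated, untreated):
GEN_CM = ((440, 65), (109, 133))
TRAIN_CM = ((1270, 177), (357, 389))


def labels_from_cm(cm):
    """Build label vectors whose tally reproduces a 2x2 confusion matrix."""
    (tt, tu), (ut, uu) = cm
    y_true = [1] * (tt + tu) + [0] * (ut + uu)
    y_pred = [1] * tt + [0] * tu + [1] * ut + [0] * uu
    return np.array(y_true), np.array(y_pred)


def mann_whitney_auc(y, s):
    """O(n^2) pairwise oracle: concordant pairs + half ties over cross pairs."""
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_reference_generalisation_tally(self):
        y_true, y_pred = labels_from_cm(GEN_CM)
        cm = confusion_matrix(y_true, y_pred)
        assert cm.counts == GEN_CM
        assert cm.n == 747

    def test_perfect_classifier_has_zero_off_diagonal(self):
        y = np.array([1, 1, 0, 0, 1])
        cm = confusion_matrix(y, y)
        assert cm.counts == ((3, 0), (0, 2))

    def test_matches_enumeration_oracle(self, rng):
        y_true = rng.integers(0, 2, size=20)
        y_pred = rng.integers(0, 2, size=20)
        cm = confusion_matrix(y_true, y_pred)
        for i, ci in enumerate((1, 0)):
            for j, cj in enumerate((1, 0)):
                brute = sum(1 for t, p in zip(y_true, y_pred) if t == ci and p == cj)
                assert cm.counts[i][j] == brute

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [1])
        with pytest.raises(ValueError):
            confusion_matrix([0, 2], [1, 1])
        with pytest.raises(ValueError):
            ConfusionMatrix(((1, -1), (0, 0)))


class TestCCRAndMS:
    def test_reference_generalisation_values(self):
        cm = ConfusionMatrix(GEN_CM)
        assert ccr(cm) == pytest.approx(573 / 747)
        assert round(ccr(cm), 3) == 0.767
        assert min_sensitivity(cm) == pytest.approx(133 / 242)
        assert min_sensitivity(cm) == pytest.approx(0.550, abs=1e-3)

    def test_reference_training_values(self):
        cm = ConfusionMatrix(TRAIN_CM)
        assert ccr(cm) == pytest.approx(1659 / 2193)
        # the published rounded training metrics (0.757, 0.522) sit within
        # a thousandth of the exact ratios from the printed counts
        assert ccr(cm) == pytest.approx(0.757, abs=1e-3)
        assert min_sensitivity(cm) == pytest.approx(389 / 746)
        assert min_sensitivity(cm) == pytest.approx(0.522, abs=1e-3)

    def test_degenerate_classifiers(self):
        assert ccr(ConfusionMatrix(((5, 0), (0, 7)))) == 1.0
        # everything predicted treated: untreated sensitivity collapses to 0
        assert min_sensitivity(ConfusionMatrix(((5, 0), (7, 0)))) == 0.0

    def test_empty_or_one_sided_inputs_rejected(self):
        with pytest.raises(ValueError):
            ccr(ConfusionMatrix(((0, 0), (0, 0))))
        with pytest.raises(ValueError):
            min_sensitivity(ConfusionMatrix(((3, 1), (0, 0))))

    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_ccr_is_prevalence_weighted_mean_of_sensitivities(self, counts):
        tt, tu, ut, uu = counts
        if tt + tu == 0 or ut + uu == 0:
            return
        cm = ConfusionMatrix(((tt, tu), (ut, uu)))
        s_t, s_u = sensitivities(cm)
        n_t, n_u = tt + tu, ut + uu
        weighted = (n_t * s_t + n_u * s_u) / (n_t + n_u)
        assert ccr(cm) == pytest.approx(weighted, abs=1e-12)
        assert min(s_t, s_u) <= ccr(cm) <= max(s_t, s_u) + 1e-12


class TestAUC:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_constant_scores_give_half(self):
        y = np.array([0, 1, 0, 1, 1])
        assert auc(y, np.full(5, 0.3)) == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(100):
            y = rng.integers(0, 2, size=30)
            if len(np.unique(y)) < 2:
                continue
            # coarse grid forces plenty of ties
            s = rng.integers(0, 6, size=30) / 5.0
            assert auc(y, s) == pytest.approx(mann_whitney_auc(y, s), abs=1e-12)

    def test_complement_under_score_negation(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)  # continuous, tie-free
        assert auc(y, s) + auc(y, -s) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_monotone_score_transform(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.uniform(0.01, 0.99, size=50)
        assert auc(y, s) == pytest.approx(auc(y, np.log(s / (1 - s))), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(5), np.linspace(0, 1, 5))


class TestROC:
    def test_endpoints(self, rng):
        y = rng.integers(0, 2, size=25)
        y[:2] = [0, 1]
        pts = roc_points(y, rng.normal(size=25))
        assert pts[0] == (0.0, 0.0)
        assert pts[-1] == (1.0, 1.0)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_perfect_separation_passes_through_ideal_corner(self):
        y = np.array([0, 0, 1, 1])
        assert (0.0, 1.0) in roc_points(y, np.array([0.1, 0.2, 0.8, 0.9]))

    def test_trapezoid_of_points_equals_auc(self, rng):
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        s = rng.integers(0, 10, size=60) / 9.0
        pts = roc_points(y, s)
        area = np.trapezoid([p[1] for p in pts], [p[0] for p in pts])
        assert area == pytest.approx(auc(y, s), abs=1e-12)


class TestPrecisionRecall:
    def test_perfect_scores_give_unit_area(self):
        y = np.array([0, 0, 1, 1])
        _, area = pr_points_and_auc(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert area == pytest.approx(1.0)

    def test_constant_scores_precision_equals_prevalence(self):
        y = np.array([1, 0, 1, 1, 0])
        pts, area = pr_points_and_auc(y, np.full(5, 0.7))
        prevalence = 0.6
        assert all(p == pytest.approx(prevalence) for _, p in pts)
        assert area == pytest.approx(prevalence)

    def test_matches_threshold_enumeration_oracle(self, rng):
        y = rng.integers(0, 2, size=30)
        y[0] = 1
        s = rng.integers(0, 5, size=30) / 4.0
        pts, _ = pr_points_and_auc(y, s)
        P = y.sum()
        expected = {(0.0, None)}
        for thr in np.unique(s):
            pred = s >= thr
            tp = int((y & pred).sum())
            expected.add((tp / P, tp / pred.sum()))
        got = set(pts[1:])
        assert got == {e for e in expected if e[1] is not None}

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_points_and_auc(np.zeros(4), np.linspace(0, 1, 4))


class TestAgainstSklearn:
    """Cross-checks against an independent reference implementation."""

    def test_auc_matches_roc_auc_score(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            y = rng.integers(0, 2, size=40)
            y[:2] = [0, 1]
            s = rng.integers(0, 8, size=40) / 7.0
            assert auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_pr_auc_close_to_sklearn_average_precision(self, rng):
        # different integration conventions (trapezoid vs step), so only
        # closeness is expected, not identity
        from sklearn.metrics import average_precision_score

        y = rng.integers(0, 2, size=300)
        y[0] = 1
        s = rng.uniform(size=300) + 0.5 * y
        _, area = pr_points_and_auc(y, s)
        assert area == pytest.approx(average_precision_score(y, s), abs=0.02)


class TestReport:
    def test_report_consistency(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        s = rng.uniform(size=100)
        rep = compute_report(y, s, n_connections=9)
        assert rep.ms == min(rep.sensitivity_treated, rep.sensitivity_untreated)
        assert rep.ccr == pytest.approx(ccr(rep.confusion))
        assert rep.auc == pytest.approx(auc(y, s))
        assert rep.n_connections == 9
        d = rep.to_dict()
        assert d["confusion"] == [list(r) for r in rep.confusion.counts]
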