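"""Confusion matrix and metric formulas, with brute-force oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nephroseg import (
    LabelMask,
    UNANNOTATED,
    class_metrics,
    confusion_matrix,
    f1_from_precision_recall,
    macro_summary,
    row_normalize,
)
from nephroseg.evaluate import ConfusionMatrix


def _mask(labels, factor=1):
    return LabelMask(np.asarray(labels, dtype=np.uint8), downsample_factor=factor)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, schema):
        labels = np.full((10, 10), 3)
        cm = confusion_matrix(_mask(labels), _mask(labels), schema)
        assert cm.counts[3, 3] == 100 and cm.total == 100

    def test_disjoint_masks_are_off_diagonal(self, schema):
        gt = np.full((10, 10), 7)
        pred = np.full((10, 10), 8)
        cm = confusion_matrix(_mask(gt), _mask(pred), schema)
        assert cm.counts[7, 8] == 100 and cm.counts.sum() == 100

    def test_unannotated_truth_excluded(self, schema):
        gt = np.full((10, 10), UNANNOTATED)
        gt[:2] = 1
        cm = confusion_matrix(_mask(gt), _mask(np.ones((10, 10))), schema)
        assert cm.total == 20

    def test_alignment_modes(self, schema, injured_section):
        _, mask, _ = injured_section
        pred8 = _mask(mask.labels[::8, ::8], factor=8)
        down = confusion_matrix(mask, pred8, schema, align="downsample-gt")
        assert down.total == pred8.labels.size
        up = confusion_matrix(mask, pred8, schema, align="upsample-pred")
        assert up.total == mask.labels.size

    def test_grid_mismatch_raises(self, schema):
        with pytest.raises(ValueError):
            confusion_matrix(
                _mask(np.zeros((8, 8))), _mask(np.zeros((9, 9))), schema
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_per_pixel_brute_force(self, schema, seed):
        """One-vs-rest TP/FP/FN/TN from the matrix == direct pixel counting."""
        rng = np.random.default_rng(seed)
        k = schema.n_classes
        gt = rng.integers(0, k, (32, 32)).astype(np.uint8)
        gt[rng.random((32, 32)) < 0.2] = UNANNOTATED
        pred = rng.integers(0, k, (32, 32)).astype(np.uint8)
        cm = confusion_matrix(_mask(gt), _mask(pred), schema)
        valid = gt != UNANNOTATED
        for cid in range(k):
            tp = int(((gt == cid) & (pred == cid) & valid).sum())
            fp = int(((gt != cid) & (pred == cid) & valid).sum())
            fn = int(((gt == cid) & (pred != cid) & valid).sum())
            tn = int(((gt != cid) & (pred != cid) & valid).sum())
            assert cm.one_vs_rest(cid) == (tp, fp, fn, tn)


counts_matrices = st.integers(2, 6).flatmap(
    lambda k: st.lists(
        st.lists(st.integers(0, 1000), min_size=k, max_size=k),
        min_size=k,
        max_size=k,
    )
)


class TestRowNormalize:
    def test_identity_prediction_is_100_diagonal(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30]))
        pct = row_normalize(cm)
        assert np.allclose(np.diag(pct), 100.0)

    def test_printed_example_85_percent(self):
        # 85 of 100 truth pixels kept on the diagonal reads as 85%
        counts = np.array([[85, 15], [0, 50]])
        assert row_normalize(ConfusionMatrix(counts))[0, 0] == pytest.approx(85.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(counts_matrices)
    def test_rows_sum_to_100(self, rows):
        cm = ConfusionMatrix(np.array(rows))
        pct = row_normalize(cm)
        totals = cm.counts.sum(axis=1)
        for i, t in enumerate(totals):
            if t == 0:
                assert np.isnan(pct[i]).all()
            else:
                assert pct[i].sum() == pytest.approx(100.0, abs=1e-6)


class TestClassMetrics:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(counts_matrices)
    def test_f1_identity_on_integer_counts(self, rows):
        """2PR/(P+R) == 2TP/(2TP+FP+FN) exactly, in rational arithmetic."""
        cm = ConfusionMatrix(np.array(rows))
        for cid in range(cm.n_classes):
            tp, fp, fn, _ = cm.one_vs_rest(cid)
            if 2 * tp + fp + fn == 0 or tp + fp == 0 or tp + fn == 0:
                continue
            p = Fraction(tp, tp + fp)
            r = Fraction(tp, tp + fn)
            if p + r == 0:
                continue
            assert 2 * p * r / (p + r) == Fraction(2 * tp, 2 * tp + fp + fn)

    def test_absent_class_has_undefined_recall_specificity_one(self, schema):
        gt = np.full((10, 10), 3)
        m = class_metrics(confusion_matrix(_mask(gt), _mask(gt), schema))
        assert m.recall[5] is None  # class 5 absent from truth and prediction
        assert m.specificity[5] == 1.0
        assert m.precision[5] is None

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, (4, 4))
        cm = ConfusionMatrix(counts)
        perm = np.array([2, 0, 3, 1])
        cm_p = ConfusionMatrix(counts[np.ix_(perm, perm)])
        m, m_p = class_metrics(cm), class_metrics(cm_p)
        for i, j in enumerate(perm):
            assert m_p.f1[i] == m.f1[j]
            assert m_p.precision[i] == m.precision[j]
            assert m_p.specificity[i] == m.specificity[j]


class TestMacroSummary:
    def test_all_ones(self):
        cm = ConfusionMatrix(np.diag([5, 5]))
        s = macro_summary(class_metrics(cm), cm)
        assert s.macro_f1 == s.weighted_f1 == 1.0

    def test_equal_support_mean(self):
        # class 0: recall 0.8 (40/50); class 1: recall 1.0 (50/50)
        counts = np.array([[40, 10], [0, 50]])
        cm = ConfusionMatrix(counts)
        s = macro_summary(class_metrics(cm), cm)
        assert s.macro_recall == pytest.approx(0.9)
        assert s.weighted_recall == pytest.approx(0.9)

    def test_weighting_shifts_toward_larger_class(self):
        # class 0: recall 0.5 on 20 px; class 1: recall 1.0 on 180 px
        counts = np.array([[10, 10], [0, 180]])
        cm = ConfusionMatrix(counts)
        s = macro_summary(class_metrics(cm), cm)
        assert s.macro_recall == pytest.approx(0.75)
        assert s.weighted_recall == pytest.approx((0.5 * 20 + 1.0 * 180) / 200)
        assert s.weighted_recall > s.macro_recall


def test_f1_from_precision_recall_harmonic_mean():
    assert f1_from_precision_recall(1.0, 1.0) == 1.0
    assert f1_from_precision_recall(0.0, 0.0) is None
    assert f1_from_precision_recall(0.5, 1.0) == pytest.approx(2 / 3)
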