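"""FOV grading, the semi-quantitative scorer and rank correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nephroseg import (
    LabelMask,
    ScorePair,
    correlate,
    grade_fov,
    semiquant_score,
)
from nephroseg.scoring import compare_cohort


def _mask(labels, factor=1):
    return LabelMask(np.asarray(labels, dtype=np.uint8), downsample_factor=factor)


class TestGradeFov:
    @pytest.mark.parametrize(
        "fraction, grade",
        [
            (0.0, 0),
            (0.10, 1),
            (0.25, 1),
            (0.26, 2),
            (0.50, 2),
            (0.60, 3),
            (0.75, 3),
            (0.76, 4),
            (1.0, 4),
        ],
    )
    def test_bin_membership(self, fraction, grade):
        assert grade_fov(fraction) == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade_fov(-0.1)
        with pytest.raises(ValueError):
            grade_fov(1.01)

    def test_monotone_and_exhaustive_on_sweep(self):
        fractions = np.linspace(0.0, 1.0, 501)
        grades = [grade_fov(f) for f in fractions]
        assert all(g in {0, 1, 2, 3, 4} for g in grades)
        assert all(a <= b for a, b in zip(grades, grades[1:]))
        assert grades[0] == 0 and grades[-1] == 4


class TestSemiQuantScore:
    def test_healthy_section_all_grades_zero(self, schema):
        labels = np.full((200, 200), 3)
        s = semiquant_score(_mask(labels), schema, fov_size=40, seed=1)
        assert s.fov_grades == (0,) * 10 and s.mean_grade == 0.0

    def test_uniform_30_percent_damage_grades_2(self, schema):
        # period-10 stripes: any 40-wide window holds exactly 30% casts
        labels = np.full((200, 200), 3, dtype=np.uint8)
        labels[:, np.arange(200) % 10 < 3] = 7
        s = semiquant_score(_mask(labels), schema, fov_size=40, seed=2)
        assert s.fov_grades == (2,) * 10 and s.mean_grade == 2.0

    def test_same_seed_reproduces_origins_and_grades(self, schema, injured_section):
        _, mask, _ = injured_section
        a = semiquant_score(mask, schema, fov_size=64, seed=9)
        b = semiquant_score(mask, schema, fov_size=64, seed=9)
        assert a == b

    def test_region_mask_restricts_fovs(self, schema):
        labels = np.full((200, 200), 3, dtype=np.uint8)
        labels[:100] = 7  # damaged upper half
        region = np.zeros((200, 200), dtype=bool)
        region[120:200] = True  # restrict centres to the healthy lower half
        s = semiquant_score(
            _mask(labels), schema, fov_size=20, seed=0, region_mask=region
        )
        assert s.mean_grade == 0.0
        assert all(y >= 100 for _, y in s.fov_origins)

    def test_oversized_fov_and_empty_region_rejected(self, schema):
        labels = np.full((50, 50), 3)
        with pytest.raises(ValueError):
            semiquant_score(_mask(labels), schema, fov_size=64)
        with pytest.raises(ValueError):
            semiquant_score(
                _mask(labels), schema, fov_size=10,
                region_mask=np.zeros((50, 50), dtype=bool),
            )


def _rank_pearson(x, y):
    """Brute-force Spearman: Pearson correlation of mean-ranked data."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        pos = np.arange(1.0, len(v) + 1)
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            r[order[i:j]] = pos[i:j].mean()
            i = j
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestCorrelate:
    @staticmethod
    def _pairs(x, y):
        return [ScorePair(i, float(a), float(b)) for i, (a, b) in enumerate(zip(x, y))]

    def test_monotone_transform_gives_one(self):
        x = [1, 2, 3, 4, 5]
        r, p = correlate(self._pairs([10 * v for v in x], [v**2 / 10 for v in x]))
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_reversal_gives_minus_one(self):
        r, _ = correlate(self._pairs([0, 10, 20, 30], [4, 3, 2, 1]))
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks of y are (2,1,4,3,5): sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
        r, _ = correlate(self._pairs([1, 2, 3, 4, 5], [2.0, 1.0, 3.5, 3.0, 4.0]))
        assert r == pytest.approx(0.8)
        assert _rank_pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate(self._pairs([1, 2, 3], [2, 2, 2]))

    def test_pearson_method(self):
        x = [0, 10, 20, 30, 40]
        y = [0.0, 1.0, 2.0, 3.0, 4.0]
        r, _ = correlate(self._pairs(x, y), method="pearson")
        assert r == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8)),
            min_size=4,
            max_size=30,
        )
    )
    def test_spearman_equals_rank_pearson_with_ties(self, pts):
        x = [a for a, _ in pts]
        y = [b for _, b in pts]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        expected = _rank_pearson(x, y)
        got = stats.spearmanr(x, y).statistic
        assert got == pytest.approx(expected, abs=1e-12)


class TestCompareCohort:
    def test_small_cohort_positive_correlation(self, schema):
        rng = np.random.default_rng(0)
        sections = []
        for i, frac in enumerate([0.0, 0.1, 0.3, 0.5, 0.7]):
            labels = np.full((120, 120), 3, dtype=np.uint8)
            damage = rng.random((120, 120)) < frac
            labels[damage] = 8
            sections.append((i, _mask(labels)))
        table, r, p = compare_cohort(sections, schema, fov_size=40, seed=0)
        assert len(table) == 5
        assert r > 0.9

    def test_identical_sections_undefined(self, schema):
        labels = np.full((120, 120), 3, dtype=np.uint8)
        labels[:40] = 7
        sections = [(i, _mask(labels.copy())) for i in range(4)]
        with pytest.raises(ValueError):
            compare_cohort(sections, schema, fov_size=40, seed=0)

    def test_empty_cohort(self, schema):
        with pytest.raises(ValueError):
            compare_cohort([], schema)
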