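"""Diagnostic-performance and contingency statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinexmed import (
    ConfusionMatrix,
    ContingencyTable,
    chi_square_homogeneity,
    counts_from_percentages,
    diagnostic_performance,
    fisher_exact_2x2,
    welch_t,
)
from retinexmed.clinical_stats import round2
from retinexmed.errors import (
    AmbiguityError,
    DegenerateTableError,
    DomainError,
    ShapeError,
    UndefinedRateError,
)


def hypergeom_fisher_oracle(table):
    """Independent oracle: full hypergeometric enumeration with math.comb."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, col1)
    probs = {}
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        probs[k] = math.comb(row1, k) * math.comb(n - row1, col1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestDiagnosticPerformance:
    def test_direct_ratios(self):
        cm = ConfusionMatrix(tp=9, fp=0, tn=10, fn=1)
        assert diagnostic_performance(cm) == (90.00, 100.00, 95.00)

    def test_perfect_classifier(self):
        cm = ConfusionMatrix(tp=5, fp=0, tn=5, fn=0)
        assert diagnostic_performance(cm) == (100.00, 100.00, 100.00)

    def test_degenerate_detector(self):
        cm = ConfusionMatrix(tp=0, fp=0, tn=5, fn=5)
        assert diagnostic_performance(cm) == (0.00, 100.00, 50.00)

    def test_two_decimal_rounding(self):
        cm = ConfusionMatrix(tp=31, fp=4, tn=31, fn=4)  # 31/35 = 88.5714...
        sens, spec, acc = diagnostic_performance(cm)
        assert sens == 88.57 and spec == 88.57

    def test_empty_positive_margin_rejected(self):
        with pytest.raises(UndefinedRateError):
            diagnostic_performance(ConfusionMatrix(tp=0, fp=3, tn=4, fn=0))

    def test_accuracy_is_prevalence_weighted_mean(self, rng):
        for _ in range(10):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 40, 4))
            cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
            sens = 100 * tp / (tp + fn)
            spec = 100 * tn / (tn + fp)
            prev = (tp + fn) / cm.total
            _, _, acc = diagnostic_performance(cm)
            assert acc == pytest.approx(prev * sens + (1 - prev) * spec, abs=0.005)

    def test_negative_count_rejected(self):
        with pytest.raises(DomainError):
            ConfusionMatrix(tp=-1, fp=0, tn=1, fn=0)


class TestChiSquare:
    def test_identical_rows_give_zero_statistic(self):
        stat, df, p = chi_square_homogeneity([[10, 5, 2], [10, 5, 2]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_healing_grade_table_oracle(self):
        """Oracle: hand-computed expected counts (margins /2) and chi-square
        sum; p from the df=2 closed form exp(-x/2)."""
        table = [[31, 3, 1], [16, 14, 5]]
        expected_cells = [23.5, 8.5, 3.0]
        stat_hand = sum(
            (obs - e) ** 2 / e
            for row in table
            for obs, e in zip(row, expected_cells)
        )
        stat, df, p = chi_square_homogeneity(table)
        assert stat == pytest.approx(stat_hand, abs=1e-9)
        assert stat == pytest.approx(14.57, abs=0.01)
        assert df == 2
        assert p == pytest.approx(math.exp(-stat_hand / 2), rel=1e-9)
        assert p == pytest.approx(6.9e-4, abs=1e-4)

    def test_diagonal_2x2(self):
        stat, df, p = chi_square_homogeneity([[10, 0], [0, 10]])
        assert df == 1
        assert stat == pytest.approx(20.0, abs=1e-9)

    def test_permutation_invariance(self, rng):
        table = rng.integers(1, 30, (3, 4))
        stat, df, p = chi_square_homogeneity(table)
        shuffled = table[[2, 0, 1]][:, [3, 1, 0, 2]]
        stat2, df2, p2 = chi_square_homogeneity(shuffled)
        assert stat2 == pytest.approx(stat, rel=1e-12) and df2 == df

    def test_zero_expected_count_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_homogeneity([[0, 5], [0, 7]])


class TestFisherExact:
    def test_secondary_suture_table_matches_enumeration(self):
        table = [[2, 33], [4, 31]]
        p = fisher_exact_2x2(table)
        assert p == pytest.approx(hypergeom_fisher_oracle(table), rel=1e-9)
        assert p == pytest.approx(0.673, abs=0.001)

    def test_equal_rows_give_p_one(self):
        assert fisher_exact_2x2([[8, 12], [8, 12]]) == pytest.approx(1.0)

    def test_extreme_diagonal_table(self):
        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_row_swap_invariance(self, rng):
        for _ in range(5):
            t = rng.integers(0, 25, (2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t[::-1]), rel=1e-9)

    def test_p_in_unit_interval(self, rng):
        for _ in range(10):
            t = rng.integers(0, 40, (2, 2)) + np.eye(2, dtype=int)
            p = fisher_exact_2x2(t)
            assert 0 < p <= 1

    def test_non_2x2_rejected(self):
        with pytest.raises(ShapeError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])


class TestCountsFromPercentages:
    def test_healing_grade_study_group(self):
        assert counts_from_percentages([88.57, 8.57, 2.86], 35) == [31, 3, 1]

    def test_healing_grade_control_group(self):
        assert counts_from_percentages([45.71, 40.00, 14.29], 35) == [16, 14, 5]

    def test_exact_halves(self):
        assert counts_from_percentages([50.00, 50.00], 10) == [5, 5]

    def test_inconsistent_sum_rejected(self):
        with pytest.raises(DomainError):
            counts_from_percentages([50.0, 20.0], 10)

    def test_ambiguous_inputs_raise(self):
        # at n=200, 0.5% resolution makes many near-ties ambiguous is not
        # guaranteed; instead force ambiguity with an impossible percentage
        with pytest.raises(AmbiguityError):
            counts_from_percentages([88.0, 12.0], 35)  # no composition prints 88.00

    @settings(deadline=None, max_examples=40)
    @given(
        n=st.integers(2, 60),
        data=st.data(),
    )
    def test_round_trip_identity(self, n, data):
        """Inverting the printed percentages of any composition recovers it."""
        k = data.draw(st.integers(2, 4))
        cuts = sorted(data.draw(
            st.lists(st.integers(0, n), min_size=k - 1, max_size=k - 1)
        ))
        counts = np.diff([0, *cuts, n]).tolist()
        percentages = [round2(100 * c / n) for c in counts]
        try:
            recovered = counts_from_percentages(percentages, n)
        except AmbiguityError:
            return  # legitimately non-unique at coarse printing resolution
        assert recovered == counts


def test_welch_t_matches_known_direction(rng):
    x = rng.normal(10.0, 1.0, 30)
    y = rng.normal(12.0, 1.0, 30)
    t, df, p = welch_t(x, y)
    assert t < 0 and p < 0.01 and df > 10


def test_round2_half_away_from_zero():
    assert round2(100 * 31 / 35) == 88.57
    assert round2(100 * 1 / 35) == 2.86
    assert round2(-100 * 1 / 35) == -2.86
    assert round2(0.125) == 0.13  # exact binary half rounds away from zero
    assert round2(-0.125) == -0.13
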