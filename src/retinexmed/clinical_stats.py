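"""Diagnostic-performance and contingency statistics for small clinical tables.

Covers the statistics used around a two-arm wound-healing comparison:
sensitivity/specificity/accuracy from a confusion matrix, the Pearson
chi-square homogeneity test on r×c count tables, the two-sided Fisher exact
test for 2×2 tables whose counts are too small for the chi-square
approximation, Welch's t for measurement data, and a utility that recovers
the underlying integer counts from percentages printed to two decimals.

Percentages follow the round-half-away-from-zero convention (so 31/35 prints
as 88.57%), which is what clinical reports almost universally use.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    AmbiguityError,
    DegenerateTableError,
    DomainError,
    ShapeError,
    UndefinedRateError,
)

__all__ = [
    "ConfusionMatrix",
    "ContingencyTable",
    "diagnostic_performance",
    "chi_square_homogeneity",
    "fisher_exact_2x2",
    "counts_from_percentages",
    "welch_t",
    "round2",
]


def round2(x: float) -> float:
    """Round to two decimals, half away from zero (clinical convention)."""
    return math.copysign(math.floor(abs(x) * 100 + 0.5) / 100, x)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positives and negatives (patients or lesions)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DomainError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise DomainError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ContingencyTable:
    """r×c table of nonnegative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: Sequence[str] | None = None
    col_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ShapeError(f"contingency table must be 2-D, got shape {self.counts.shape}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise DomainError("contingency counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise DomainError("contingency counts must be nonnegative")
        if self.counts.sum() == 0:
            raise DegenerateTableError("contingency table has zero grand total")


def diagnostic_performance(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %), each rounded to 2 decimals.

    sensitivity = 100 tp/(tp+fn); specificity = 100 tn/(tn+fp);
    accuracy = 100 (tp+tn)/total.  Requires nonempty positive and negative
    margins.
    """
    if cm.tp + cm.fn == 0:
        raise UndefinedRateError("no positive cases: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise UndefinedRateError("no negative cases: specificity undefined")
    sens = 100.0 * cm.tp / (cm.tp + cm.fn)
    spec = 100.0 * cm.tn / (cm.tn + cm.fp)
    acc = 100.0 * (cm.tp + cm.tn) / cm.total
    return round2(sens), round2(spec), round2(acc)


def _as_table(table: ContingencyTable | np.ndarray | Sequence) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return ContingencyTable(np.asarray(table)).counts


def chi_square_homogeneity(
    table: ContingencyTable | np.ndarray | Sequence,
) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity, no continuity correction.

    Returns ``(statistic, df, p)`` with expected counts from the row/column
    margins and ``df = (r-1)(c-1)``.  Any zero expected count makes the
    statistic undefined and raises :class:`DegenerateTableError`.
    """
    counts = _as_table(table)
    expected = stats.contingency.expected_freq(counts)
    if np.any(expected <= 0):
        raise DegenerateTableError("zero expected count; chi-square undefined")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact_2x2(table: ContingencyTable | np.ndarray | Sequence) -> float:
    """Two-sided Fisher exact p for a 2×2 table.

    Sums the hypergeometric probabilities of all tables (with the observed
    margins) whose probability does not exceed the observed table's.
    """
    counts = _as_table(table)
    if counts.shape != (2, 2):
        raise ShapeError(f"Fisher exact requires a 2×2 table, got shape {counts.shape}")
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def _compositions(n: int, k: int):
    """All k-tuples of nonnegative integers summing to n."""
    for cuts in itertools.combinations(range(n + k - 1), k - 1):
        prev, parts = -1, []
        for cut in cuts:
            parts.append(cut - prev - 1)
            prev = cut
        parts.append(n + k - 2 - prev)
        yield tuple(parts)


def counts_from_percentages(percentages: Sequence[float], n: int) -> list[int]:
    """Recover the integer counts behind percentages printed to two decimals.

    Exhaustively searches the compositions of ``n`` and returns the unique
    count vector whose two-decimal rounded percentages match the input
    (within printing precision).  Raises :class:`AmbiguityError` when no
    composition or more than one composition matches.
    """
    if n <= 0:
        raise DomainError(f"group size must be positive, got {n}")
    k = len(percentages)
    if k < 1:
        raise DomainError("need at least one percentage")
    if abs(sum(percentages) - 100.0) > 0.5 * k:
        raise DomainError(f"percentages sum to {sum(percentages):g}, not ~100")
    target = [round2(p) for p in percentages]
    matches = []
    for parts in _compositions(n, k):
        if all(abs(round2(100.0 * c / n) - t) < 0.005 for c, t in zip(parts, target)):
            matches.append(list(parts))
    if not matches:
        raise AmbiguityError(f"no integer counts over n={n} print as {percentages}")
    if len(matches) > 1:
        raise AmbiguityError(
            f"percentages {percentages} over n={n} are ambiguous: {matches}"
        )
    return matches[0]


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t test for (mean ± sd) measurement data.

    Returns ``(t, df, p)``; routine wrapper provided for completeness of the
    clinical workflow.
    """
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
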