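"""Bivariate statistics: Pearson correlation, 2x2 chi-square and Fisher
exact tests, and mean +/- standard error descriptives.

Conventions match the analysis style these tools support: the chi-square is
the uncorrected Pearson statistic (no Yates continuity correction), the
Fisher test is two-sided by the probability-mass method (summing all tables
with fixed margins whose hypergeometric probability does not exceed the
observed one), significance is declared at alpha = 0.05 and no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateTableError,
    ParameterError,
    UndefinedCorrelationError,
)

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single significance test."""

    statistic: float
    p_value: float
    significant: bool
    df: Optional[int] = None
    name: str = ""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table; rows are groups, columns outcome classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("contingency counts must be non-negative")
        if self.total == 0:
            raise DegenerateTableError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable2x2):
        return table.to_array()
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ParameterError("contingency counts must be non-negative")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float], alpha: float = ALPHA) -> TestResult:
    """Pearson correlation with a two-sided p-value from the t transform
    on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ParameterError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: an input series has zero variance"
        )
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        df=n - 2,
        name="pearson_r",
    )


def chi_square_2x2(table, alpha: float = ALPHA) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table (1 df).

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the p-value comes from
    the chi-square distribution with one degree of freedom.
    """
    arr = _as_table(table)
    (a, b), (c, d) = arr
    margins = [a + b, c + d, a + c, b + d]
    if min(margins) == 0:
        raise DegenerateTableError("a margin of the 2x2 table is zero")
    n = arr.sum()
    chi2 = n * float(a * d - b * c) ** 2 / float(np.prod(margins, dtype=np.float64))
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(chi2, p, p < alpha, df=1, name="chi_square")


def fisher_exact_2x2(table, alpha: float = ALPHA) -> TestResult:
    """Two-sided Fisher exact test (probability-mass method).

    The reported statistic is the sample odds ratio (inf when ``b*c`` is 0).
    """
    arr = _as_table(table)
    (a, b), (c, d) = arr
    if min(a + b, c + d, a + c, b + d) == 0:
        raise DegenerateTableError("a margin of the 2x2 table is zero")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(float(odds), float(p), bool(p < alpha), name="fisher_exact")


def mean_se(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD with n-1 denominator over sqrt n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ParameterError(f"need at least 2 values, got {arr.size}")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))
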