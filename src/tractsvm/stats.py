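"""Cohort comparison statistics from printed group summaries or raw data.

Reproduces the demographic-table conventions: pooled-variance two-sample
t-tests computed from (n, mean, SD) summaries (df = n1 + n2 - 2), and the
Pearson chi-square on 2x2 group-by-trait tables, uncorrected by default
(the Yates continuity correction is available as a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupSummary", "two_sample_t", "chi_square_2x2"]


@dataclass(frozen=True)
class GroupSummary:
    """One variable in one group: count, mean, standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def two_sample_t(
    g1: GroupSummary, g2: GroupSummary, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test from summaries: (t, df, two-sided p).

    Pooled-variance by default (df = n1 + n2 - 2); Welch's unequal-variance
    form with the flag. The statistic is g1 minus g2.
    """
    if g1.sd == 0 and g2.sd == 0:
        raise ValueError("both group SDs are zero; t-test undefined")
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=not welch
    )
    if welch:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    else:
        df = g1.n + g2.n - 2
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(
    table: np.ndarray, continuity_correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table: (X^2, df=1, p).

    ``table`` is [[a, b], [c, d]] (group x binary trait). All margins must
    be positive. The continuity (Yates) correction is off by default.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(chi2), int(df), float(p)
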