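"""Demographic group comparisons: t-tests from raw values or summaries.

The cohort-characteristics layer compares case and control means with a
two-tailed t-test, square-root transforming count variables (gravidity,
parity) first. Both the classical pooled-variance Student test and the
Welch unequal-variance test are available; tests can be computed either
from raw vectors or from printed (mean, SD, n) summaries, and the two
routes agree exactly when the summaries derive from the same raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary statistics for one group: mean, SD, n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=x.size)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float  # two-tailed


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, equal_var: bool = True
) -> TTestResult:
    """Two-tailed t-test from (mean, SD, n) summaries.

    ``equal_var=True`` gives the classical pooled-variance Student test;
    ``False`` gives Welch with Satterthwaite degrees of freedom.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0)
        raise ValueError("zero variance in both groups with unequal means")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if equal_var:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = float(a.n + b.n - 2)
    else:
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Welch unequal-variance t-test from summaries."""
    return t_test_from_summary(a, b, equal_var=False)


def student_t_from_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Classical pooled-variance Student t-test from summaries."""
    return t_test_from_summary(a, b, equal_var=True)


def t_test_from_values(a, b, equal_var: bool = True) -> TTestResult:
    """Two-tailed t-test from raw vectors (via the summary route)."""
    return t_test_from_summary(
        GroupSummary.from_values(a), GroupSummary.from_values(b), equal_var=equal_var
    )


def sqrt_count_test(counts_a, counts_b, equal_var: bool = False) -> TTestResult:
    """t-test on square-root transformed count data (gravidity, parity)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    return t_test_from_values(np.sqrt(a), np.sqrt(b), equal_var=equal_var)


def significance_flag(p: float, alpha: float = 0.05) -> bool:
    """Strict threshold: p < alpha is significant, p == alpha is not."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return p < alpha
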