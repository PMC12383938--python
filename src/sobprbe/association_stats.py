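"""Pearson LET-RBE correlation and t-test comparisons of surviving fractions.

Correlations pair each SOBP-window column's dose-averaged LET with its RBE
(n = 8 by default) and report the two-tailed p from the exact t reference
distribution with n - 2 degrees of freedom.  Three two-sample t-test variants
(paired, Welch, pooled) are exposed because published comparisons rarely say
which was used; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_tailed: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_two_tailed: float
    df: float
    variant: str


def pearson_r(x, y) -> CorrelationResult:
    """Pearson correlation with two-tailed p from t = r*sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need n >= 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_two_tailed=float(res.pvalue), n=n)


def t_test(a, b, variant: str = "pooled") -> TTestResult:
    """Two-tailed two-sample t-test: ``paired``, ``welch`` or ``pooled``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if variant == "paired":
        if a.shape != b.shape:
            raise DegenerateInputError("paired test requires equal-length samples")
        if a.size < 2:
            raise DegenerateInputError("paired test requires n >= 2 pairs")
        if np.all(a == b):
            # zero difference everywhere: no evidence against equality
            return TTestResult(0.0, 1.0, float(a.size - 1), variant)
        res = stats.ttest_rel(a, b)
        df = a.size - 1
    elif variant in ("welch", "pooled"):
        if a.size < 2 or b.size < 2:
            raise DegenerateInputError("each group needs n >= 2")
        res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
        df = float(res.df)
    else:
        raise ValueError("variant must be 'paired', 'welch' or 'pooled'")
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):
        raise DegenerateInputError("degenerate samples (zero variance in both groups)")
    # identical groups give p exactly 1 rather than nan-adjacent values
    return TTestResult(statistic=stat, p_two_tailed=min(p, 1.0), df=float(df), variant=variant)
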