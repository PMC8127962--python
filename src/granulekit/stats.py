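"""Inferential statistics: t tests, one-way ANOVA with post hoc Tukey HSD, SEM.

The test procedures are written out explicitly (pooled-variance t, Tukey-Kramer
studentized range) rather than delegated wholesale, so that each statistic is
checkable against an independent Monte-Carlo oracle.  Distribution tail areas
are evaluated numerically via :mod:`scipy.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _sps


@dataclass
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    paired: bool
    degenerate: bool = False  # zero variance with equal means

    @property
    def stars(self) -> str:
        return _stars(self.pvalue)


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    pvalue: float

    @property
    def stars(self) -> str:
        return _stars(self.pvalue)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    pvalue: float
    mse: float
    comparisons: list[TukeyComparison] = field(default_factory=list)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"SEM requires n >= 2, got n={x.size}")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> TTestResult:
    """Two-sided Student t test.

    Unpaired uses the classic pooled-variance statistic (``welch=True`` for the
    unequal-variance form); paired reduces to a one-sample test on differences.
    Zero variance with equal means is reported as t=0, p=1 with a degeneracy
    flag rather than an error.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t test requires n >= 2 per sample")
    if paired:
        if x.size != y.size:
            raise ValueError(
                f"paired t test requires equal n, got {x.size} and {y.size}"
            )
        d = x - y
        sd = np.std(d, ddof=1)
        df = float(d.size - 1)
        if sd == 0.0:
            if np.mean(d) == 0.0:
                return TTestResult(0.0, df, 1.0, True, degenerate=True)
            raise ValueError("zero variance of differences with nonzero mean")
        t = float(np.mean(d) / (sd / math.sqrt(d.size)))
    elif welch:
        v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
        n1, n2 = x.size, y.size
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            if np.mean(x) == np.mean(y):
                return TTestResult(0.0, float(n1 + n2 - 2), 1.0, False, degenerate=True)
            raise ValueError("zero variance with unequal means")
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        t = float((np.mean(x) - np.mean(y)) / math.sqrt(se2))
    else:
        n1, n2 = x.size, y.size
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
        if sp2 == 0.0:
            if np.mean(x) == np.mean(y):
                return TTestResult(0.0, df, 1.0, False, degenerate=True)
            raise ValueError("zero pooled variance with unequal means")
        t = float((np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / n1 + 1 / n2)))
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return TTestResult(t, df, min(p, 1.0), paired)


def anova_tukey(
    groups: dict[str, Sequence[float]],
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA with post hoc Tukey HSD pairwise comparisons.

    The Tukey statistic for groups i, j is
    ``q = |mean_i - mean_j| / sqrt(MSE * (1/n_i + 1/n_j) / 2)``
    (Tukey-Kramer for unequal n) and the adjusted p value is the upper tail of
    the studentized-range distribution with k groups and the ANOVA residual df.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    names = list(groups)
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has n={v.size} < 2")
    k = len(names)
    ns = {g: v.size for g, v in data.items()}
    n_total = sum(ns.values())
    grand = sum(v.sum() for v in data.values()) / n_total
    ss_between = sum(ns[g] * (data[g].mean() - grand) ** 2 for g in names)
    ss_within = sum(((data[g] - data[g].mean()) ** 2).sum() for g in names)
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    if mse == 0.0:
        if ss_between == 0.0:
            comps = [
                TukeyComparison(a, b, 0.0, 0.0, 1.0)
                for a, b in combinations(names, 2)
            ]
            return AnovaResult(0.0, df_b, df_w, 1.0, 0.0, comps)
        raise ValueError("zero within-group variance with unequal group means")
    F = (ss_between / df_b) / mse
    p_overall = float(_sps.f.sf(F, df_b, df_w))

    comps = []
    for a, b in combinations(names, 2):
        diff = float(data[a].mean() - data[b].mean())
        se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]) / 2.0)
        q = abs(diff) / se
        p_adj = float(_sps.studentized_range.sf(q, k, df_w))
        comps.append(TukeyComparison(a, b, diff, q, min(max(p_adj, 0.0), 1.0)))
    return AnovaResult(float(F), df_b, df_w, p_overall, float(mse), comps)


def tukey_critical_q(k: int, df: int, alpha: float = 0.05) -> float:
    """Critical studentized-range value controlling FWER at ``alpha``."""
    return float(_sps.studentized_range.ppf(1.0 - alpha, k, df))
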