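"""Group-comparison statistics for cohort demographics and clinical scores.

Continuous variables are compared with pooled-variance two-sample Student
t-tests (computable either from raw columns or from printed group summaries,
i.e. n/mean/SD triples); categorical variables with Pearson's chi-squared
test on a 2x2 table, without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "Chi2Result",
    "UndefinedStatisticError",
    "summarize",
    "two_sample_t",
    "chi_square_2x2",
    "group_compare_table",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for these inputs."""


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / sd triple for one group, as printed in a summary table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise UndefinedStatisticError("group summary requires n >= 2")
        if self.sd < 0:
            raise UndefinedStatisticError("sd must be >= 0")


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class Chi2Result(NamedTuple):
    chi2: float
    df: int
    p: float


def summarize(values) -> GroupSummary:
    """Exact GroupSummary (sample SD, ddof=1) of a raw column."""
    v = np.asarray(values, dtype=float)
    return GroupSummary(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


def _as_summary(g) -> GroupSummary:
    return g if isinstance(g, GroupSummary) else summarize(g)


def two_sample_t(g1, g2) -> TTestResult:
    """Pooled-variance two-sample Student t-test.

    ``g1``/``g2`` may be :class:`GroupSummary` instances or raw columns.

        t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2)),
        sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)

    with df = n1 + n2 - 2 and a two-sided p-value.  When both SDs are zero
    and the means are equal, t is defined as 0.
    """
    g1, g2 = _as_summary(g1), _as_summary(g2)
    df = g1.n + g2.n - 2
    if df <= 0:
        raise UndefinedStatisticError("t-test requires n1 + n2 - 2 > 0")
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    diff = g1.mean - g2.mean
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else np.sign(diff) * np.inf
    else:
        t = diff / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TTestResult(t=float(t), df=df, p=p)


def chi_square_2x2(table) -> Chi2Result:
    """Pearson chi-squared on a 2x2 group-by-category table, no correction.

    Accepts anything coercible to a 2x2 non-negative integer array.  Raises
    :class:`UndefinedStatisticError` if any row or column margin is zero.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("zero margin: chi-squared undefined")
    res = stats.chi2_contingency(tab, correction=False)
    return Chi2Result(chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def group_compare_table(records: pd.DataFrame, group_col: str = "diagnosis",
                        groups=("control", "patient"),
                        continuous=("age", "education"),
                        categorical=(("sex", ("M", "F")),)) -> pd.DataFrame:
    """Patient-vs-control comparison table from a raw covariate frame.

    One row per variable with group means (SD) or counts, the statistic and
    its p-value; mirrors the usual "Table 1" layout of cohort papers.
    """
    g1 = records[records[group_col] == groups[0]]
    g2 = records[records[group_col] == groups[1]]
    rows = []
    for var, levels in categorical:
        tab = [[int((g[var] == lv).sum()) for lv in levels] for g in (g1, g2)]
        r = chi_square_2x2(tab)
        rows.append({
            "variable": f"{var} ({levels[0]}:{levels[1]})",
            groups[0]: f"{tab[0][0]}:{tab[0][1]}",
            groups[1]: f"{tab[1][0]}:{tab[1][1]}",
            "statistic": r.chi2, "test": "chi2", "df": r.df, "p": r.p,
        })
    for var in continuous:
        s1, s2 = summarize(g1[var]), summarize(g2[var])
        r = two_sample_t(s1, s2)
        rows.append({
            "variable": var,
            groups[0]: f"{s1.mean:.2f} ({s1.sd:.2f})",
            groups[1]: f"{s2.mean:.2f} ({s2.sd:.2f})",
            "statistic": r.t, "test": "t", "df": r.df, "p": r.p,
        })
    return pd.DataFrame(rows)
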