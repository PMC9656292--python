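"""Contingency and group-comparison statistics for subtype association reports.

Implements the four tests used in the association tables: Pearson chi-square
(no continuity correction), two-sided Fisher exact (sum of tables no more
probable than the observed one, margins fixed), Kruskal-Wallis with tie
correction, and the Mantel-Haenszel linear-by-linear trend test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_FISHER_TABLE_BUDGET = 2_000_000


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() <= 0:
            raise ValueError("contingency table total must be > 0")

    @classmethod
    def from_labels(cls, labels_a: Sequence[str], labels_b: Sequence[str]) -> "ContingencyTable":
        tab = pd.crosstab(pd.Series(labels_a), pd.Series(labels_b))
        return cls(
            [str(r) for r in tab.index],
            [str(c) for c in tab.columns],
            tab.to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def chi_square(t: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, df, upper-tail p).  Zero row/column margins are an
    error: their expected counts are undefined.
    """
    o = t.counts.astype(float)
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row/column margin — expected counts undefined")
    expected = np.outer(row, col) / o.sum()
    stat = float(((o - expected) ** 2 / expected).sum())
    df = (o.shape[0] - 1) * (o.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def _log_table_prob(counts: np.ndarray, lg_margins: float, lg_n: float) -> float:
    # log P(table | fixed margins) = sum(log row!)+sum(log col!)-log n!-sum(log cell!)
    return lg_margins - lg_n - sum(lgamma(c + 1) for c in counts.ravel())


def _enumerate_tables(row_sums, col_rem, r, partial, out_cb):
    """DFS over all nonnegative integer tables with the given margins."""
    if r == len(row_sums) - 1:
        last = col_rem
        if np.all(last >= 0) and last.sum() == row_sums[r]:
            out_cb(partial + [last.copy()])
        return
    target = row_sums[r]

    def fill(c, remaining, row):
        if c == len(col_rem) - 1:
            v = remaining
            if 0 <= v <= col_rem[c]:
                row[c] = v
                _enumerate_tables(row_sums, col_rem - row, r + 1, partial + [row.copy()], out_cb)
            return
        hi = min(col_rem[c], remaining)
        for v in range(hi + 1):
            row[c] = v
            fill(c + 1, remaining - v, row)
        row[c] = 0

    fill(0, target, np.zeros(len(col_rem), dtype=np.int64))


def _fisher_budget(row: np.ndarray, col: np.ndarray) -> float:
    # loose upper bound on table count: product over free cells of (margin+1)
    est = 1.0
    for rs in row[:-1]:
        for cs in col[:-1]:
            est *= min(rs, cs) + 1
            if est > _FISHER_TABLE_BUDGET * 64:
                return est
    return est


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p for an r x c table with fixed margins.

    Sums the hypergeometric probabilities of all tables no more probable
    than the observed one.  2x2 tables dispatch to scipy (same convention);
    larger tables are enumerated exhaustively and error out when the
    enumeration budget would be exceeded.
    """
    o = t.counts
    if o.shape == (2, 2):
        return float(stats.fisher_exact(o, alternative="two-sided")[1])
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero row/column margin")
    if _fisher_budget(row, col) > _FISHER_TABLE_BUDGET:
        raise ValueError(
            "table too large for exact enumeration — use chi_square instead"
        )
    n = int(o.sum())
    lg_margins = sum(lgamma(x + 1) for x in row) + sum(lgamma(x + 1) for x in col)
    lg_n = lgamma(n + 1)
    logp_obs = _log_table_prob(o, lg_margins, lg_n)
    total = 0.0
    eps = 1e-9  # tolerate float jitter when comparing table probabilities

    def accumulate(rows):
        nonlocal total
        tab = np.vstack(rows)
        lp = _log_table_prob(tab, lg_margins, lg_n)
        if lp <= logp_obs + eps:
            total += np.exp(lp)

    _enumerate_tables(row, col.copy(), 0, [], accumulate)
    return float(min(total, 1.0))


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis H with tie correction.

    Returns (H, df, p).  All-identical values give H = 0, p = 1.
    """
    if len(values) != len(groups):
        raise ValueError("values and group labels differ in length")
    by_group: dict[str, list[float]] = {}
    for v, g in zip(values, groups):
        by_group.setdefault(g, []).append(float(v))
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("every group needs at least 2 values")
    samples = list(by_group.values())
    df = len(samples) - 1
    if len(set(float(v) for v in values)) == 1:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), df, float(p)


def mantel_haenszel_trend(
    t: ContingencyTable,
    row_scores: Optional[Sequence[float]] = None,
    col_scores: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Mantel-Haenszel linear-by-linear association test for ordered categories.

    Statistic is (n - 1) * r^2 where r is the count-weighted Pearson
    correlation of row and column scores (defaults 1..r and 1..c); p is the
    1-df chi-squared upper tail.
    """
    o = t.counts.astype(float)
    if o.shape[0] < 2:
        raise ValueError("need at least 2 ordered rows")
    n = o.sum()
    rs = np.asarray(row_scores if row_scores is not None else np.arange(1, o.shape[0] + 1), float)
    cs = np.asarray(col_scores if col_scores is not None else np.arange(1, o.shape[1] + 1), float)
    if len(rs) != o.shape[0] or len(cs) != o.shape[1]:
        raise ValueError("score vectors must match table shape")
    w = o / n
    mu_r = float((w.sum(axis=1) * rs).sum())
    mu_c = float((w.sum(axis=0) * cs).sum())
    cov = float((w * np.outer(rs - mu_r, cs - mu_c)).sum())
    var_r = float((w.sum(axis=1) * (rs - mu_r) ** 2).sum())
    var_c = float((w.sum(axis=0) * (cs - mu_c) ** 2).sum())
    if var_r == 0 or var_c == 0:
        return 0.0, 1.0
    r = cov / np.sqrt(var_r * var_c)
    stat = float((n - 1) * r ** 2)
    p = float(stats.chi2.sf(stat, 1))
    return stat, p
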