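"""Differential expression: one-way ANOVA + SNK post hoc, t-tests, BH, FC rules.

SNK pairwise p-values use the studentized-range distribution with the
harmonic-mean group size (Tukey-Kramer-style adaptation for unbalanced
groups) and pooled within-group df.  The stepwise protocol is encoded by
monotonicity: a pair's p is the maximum over all enclosing ranges of ranked
means, so non-significance propagates inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.special import gammaln, ndtr

from mirsubnet.io_core import ExpressionMatrix, get_logger

log = get_logger("diffexpr")


def studentized_range_sf(q, k: int, df: float, n_z: int = 64, n_s: int = 48) -> np.ndarray:
    """Upper tail of the studentized range distribution, vectorized in q.

    k = 2 reduces exactly to the two-sided t tail (q = sqrt(2)|t|).  Larger k
    uses Gauss-Legendre quadrature of the classical double integral (outer
    over the scaled chi variate of the pooled SD, inner over the standard
    normal); agrees with scipy's reference implementation to ~1e-8 while
    being orders of magnitude faster on arrays.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k == 2:
        return 2.0 * stats.t.sf(q / np.sqrt(2.0), df)
    s_sd = 1.0 / np.sqrt(2.0 * df)
    s_lo, s_hi = max(1e-9, 1.0 - 12.0 * s_sd), 1.0 + 12.0 * s_sd
    xs, ws = leggauss(n_s)
    s = 0.5 * (s_hi - s_lo) * xs + 0.5 * (s_hi + s_lo)
    ws = ws * 0.5 * (s_hi - s_lo)
    # density of s = chi_df / sqrt(df)
    g = np.exp(np.log(2.0) + (df / 2.0) * np.log(df / 2.0) - gammaln(df / 2.0)
               + (df - 1.0) * np.log(s) - df * s ** 2 / 2.0)
    xz, wz = leggauss(n_z)
    z = 9.0 * xz
    wz = wz * 9.0
    phi_z = np.exp(-z ** 2 / 2.0) / np.sqrt(2.0 * np.pi)
    cdf_z = ndtr(z)
    qs = q[:, None, None] * s[None, :, None]
    inner = (cdf_z[None, None, :] - ndtr(z[None, None, :] - qs)) ** (k - 1)
    inner = k * np.einsum("z,z,qsz->qs", wz, phi_z, inner)
    cdf = np.einsum("s,s,qs->q", ws, g, inner)
    return np.clip(1.0 - cdf, 0.0, 1.0)


@dataclass
class PairwiseResult:
    snk_p: float
    fold_change: float  # >= 1; sign carried by direction
    direction: int  # +1: first group higher, -1: lower, 0: equal

    def __post_init__(self) -> None:
        if self.fold_change < 1.0 - 1e-12:
            raise ValueError("fold_change must be >= 1")


@dataclass
class DERecord:
    feature_id: str
    global_p: float
    bh_q: float = float("nan")
    pairwise: dict[tuple[str, str], PairwiseResult] = field(default_factory=dict)

    def max_fold_change(self) -> float:
        if not self.pairwise:
            return 1.0
        return max(pr.fold_change for pr in self.pairwise.values())


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj.tolist()


def _group_arrays(m: ExpressionMatrix, groups: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Column blocks per group label, ordered by sorted label."""
    col = {s: j for j, s in enumerate(m.sample_ids)}
    missing = [s for s in groups if s not in col]
    if missing:
        raise KeyError(f"group samples absent from matrix: {missing[:5]}")
    by_label: dict[str, list[int]] = {}
    for s, l in groups.items():
        by_label.setdefault(l, []).append(col[s])
    return {l: m.values[:, sorted(js)] for l, js in sorted(by_label.items())}


def _labels_of(groups) -> Mapping[str, str]:
    return groups.labels if hasattr(groups, "labels") else groups


def anova_snk(m: ExpressionMatrix, groups) -> list[DERecord]:
    """Per-feature one-way ANOVA with SNK pairwise comparisons.

    ``groups`` is a SubtypeAssignment or a sample->label mapping over a
    subset of the matrix columns.  Fold change per pair is 2^|mean diff| of
    the log2 values; direction is the sign of (first minus second) with
    group pairs ordered by sorted label.
    """
    blocks = _group_arrays(m, _labels_of(groups))
    labels = list(blocks)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {l: blocks[l].shape[1] for l in labels}
    if any(n < 2 for n in sizes.values()):
        raise ValueError("every group needs at least 2 samples")
    for l in labels:
        if np.allclose(blocks[l].var(axis=1), 0):
            raise ValueError(f"group {l!r} has zero variance across all features")

    k = len(labels)
    n_total = sum(sizes.values())
    df_within = n_total - k
    means = np.column_stack([blocks[l].mean(axis=1) for l in labels])  # F x k
    grand = np.concatenate([blocks[l] for l in labels], axis=1).mean(axis=1)
    ss_between = sum(
        sizes[l] * (means[:, i] - grand) ** 2 for i, l in enumerate(labels)
    )
    ss_within = sum(
        ((blocks[l] - means[:, i][:, None]) ** 2).sum(axis=1)
        for i, l in enumerate(labels)
    )
    mse = ss_within / df_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ss_between / (k - 1)) / mse
    global_p = np.where(mse > 0, stats.f.sf(f_stat, k - 1, df_within), 1.0)

    bh_q = np.asarray(bh_adjust(global_p.tolist()))
    snk = _snk_pairs_batch(means, sizes, labels, mse, df_within)
    records: list[DERecord] = []
    for fi, fid in enumerate(m.feature_ids):
        pairwise = {
            pair: PairwiseResult(
                snk_p=float(snk[pair][0][fi]),
                fold_change=float(snk[pair][1][fi]),
                direction=int(snk[pair][2][fi]),
            )
            for pair in snk
        }
        records.append(DERecord(fid, float(global_p[fi]), float(bh_q[fi]), pairwise))
    return records


def _snk_pairs_batch(
    means: np.ndarray, sizes: Mapping[str, int], labels: list[str],
    mse: np.ndarray, df: int,
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """SNK p/fold-change/direction arrays per unordered label pair.

    All studentized-range evaluations are batched across features per rank
    span.  The stepwise protocol is the inward max over enclosing ranges of
    the ranked means.
    """
    n_feat, k = means.shape
    size_vec = np.array([sizes[l] for l in labels], dtype=float)
    rank = np.argsort(means, axis=1, kind="stable")  # ascending per feature
    rows = np.arange(n_feat)
    ok = mse > 0
    safe_mse = np.where(ok, mse, 1.0)
    # raw p per ranked position pair (a, b)
    raw: dict[tuple[int, int], np.ndarray] = {}
    for a in range(k):
        for b in range(a + 1, k):
            i, j = rank[:, a], rank[:, b]
            n_h = 2.0 / (1.0 / size_vec[i] + 1.0 / size_vec[j])
            diff = np.abs(means[rows, j] - means[rows, i])
            q = diff / np.sqrt(safe_mse / n_h)
            p = studentized_range_sf(q, b - a + 1, df)
            raw[(a, b)] = np.where(ok, p, np.where(diff == 0, 1.0, 0.0))
    final: dict[tuple[int, int], np.ndarray] = {}
    for a in range(k):
        for b in range(a + 1, k):
            enclosing = [raw[(a2, b2)] for a2 in range(a + 1) for b2 in range(b, k)]
            final[(a, b)] = np.minimum(np.maximum.reduce(enclosing), 1.0)
    # re-index from ranked positions to label pairs per feature
    out: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    label_index = {l: i for i, l in enumerate(labels)}
    for la, lb in ((labels[i], labels[j]) for i in range(k) for j in range(i + 1, k)):
        ia, ib = label_index[la], label_index[lb]
        pos = np.argsort(rank, axis=1, kind="stable")  # feature x group -> rank pos
        a_pos, b_pos = pos[:, ia], pos[:, ib]
        lo, hi = np.minimum(a_pos, b_pos), np.maximum(a_pos, b_pos)
        p = np.empty(n_feat)
        for (a, b), arr in final.items():
            sel = (lo == a) & (hi == b)
            p[sel] = arr[sel]
        diff = means[:, ia] - means[:, ib]
        out[(la, lb)] = (p, 2.0 ** np.abs(diff), np.sign(diff))
    return out


def select_subtype_de(records: Sequence[DERecord], p_threshold: float = 0.05,
                      fc_threshold: float = 1.5, use_adjusted: bool = True) -> set[str]:
    """Features with (adjusted) global p below threshold and at least one
    pairwise fold change above threshold."""
    selected = set()
    for rec in records:
        p = rec.bh_q if use_adjusted else rec.global_p
        if p < p_threshold and rec.max_fold_change() > fc_threshold:
            selected.add(rec.feature_id)
    return selected


def two_group_de(m: ExpressionMatrix, group_a: Sequence[str],
                 group_b: Sequence[str]) -> list[DERecord]:
    """Unpaired equal-variance t-test per feature with BH adjustment.

    The pairwise slot holds the single (A, B) contrast with fold change
    2^|mean diff| and direction sign(mean_A - mean_B).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    xa = m.subset_samples(group_a).values
    xb = m.subset_samples(group_b).values
    if np.allclose(xa.var(axis=1), 0) and np.allclose(xb.var(axis=1), 0):
        raise ValueError("both groups have zero variance across all features")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p.tolist())
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    records = []
    for fi, fid in enumerate(m.feature_ids):
        pr = PairwiseResult(
            snk_p=float(p[fi]),
            fold_change=float(2.0 ** abs(diff[fi])),
            direction=int(np.sign(diff[fi])),
        )
        records.append(DERecord(fid, float(p[fi]), float(q[fi]), {("A", "B"): pr}))
    return records
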