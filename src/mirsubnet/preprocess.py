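"""Filtering and normalization for microarray-style and count-style matrices.

Order of the microarray route: presence filter -> impute undetected to the
feature's detected minimum -> quantile normalize -> median center.  The count
route applies the low-count filter and a PCA distance-based outlier screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mirsubnet.io_core import ExpressionMatrix, get_logger

log = get_logger("preprocess")


@dataclass
class FilterReport:
    n_features_in: int
    n_features_out: int
    rule: str
    thresholds: dict

    def __post_init__(self) -> None:
        if self.n_features_out > self.n_features_in:
            raise ValueError("filter cannot add features")

    def __str__(self) -> str:
        return (f"{self.rule}: {self.n_features_in} -> {self.n_features_out} "
                f"features ({self.thresholds})")


def presence_filter(m: ExpressionMatrix, fraction: float = 0.90) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep features detected in at least ``fraction`` of samples (inclusive)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if m.n_features == 0 or m.n_samples == 0:
        raise ValueError("empty expression matrix")
    detected_frac = m.detected.mean(axis=1)
    keep = np.flatnonzero(detected_frac >= fraction)
    report = FilterReport(m.n_features, len(keep), "presence_filter",
                          {"fraction": fraction})
    log.info("%s", report)
    return m.subset_features(keep), report


def impute_undetected(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace undetected cells by the feature's minimum detected value.

    Conservative floor imputation; features with no detected cell at all are
    rejected (run the presence filter first).
    """
    out = m.copy()
    for i in range(out.n_features):
        mask = out.detected[i]
        if mask.all():
            continue
        if not mask.any():
            raise ValueError(
                f"feature {out.feature_ids[i]!r} has no detected value to impute from"
            )
        out.values[i, ~mask] = out.values[i, mask].min()
    out.detected[:] = True
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the cross-sample mean of order statistics."""
    if not m.detected.all():
        raise ValueError("undetected cells present — impute before quantile normalization")
    out = m.copy()
    if out.n_samples < 2:
        return out
    order = np.argsort(out.values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(out.n_features)
    for j in range(out.n_samples):
        ranks[order[:, j], j] = rows
    mean_quantiles = np.sort(out.values, axis=0).mean(axis=1)
    out.values = mean_quantiles[ranks]
    return out


def median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature's median across samples (log-scale data)."""
    out = m.copy()
    med = np.median(np.where(out.detected, out.values, np.nan), axis=1)
    med = np.nan_to_num(med, nan=0.0)
    out.values = out.values - med[:, None]
    return out


def count_filter(
    counts: ExpressionMatrix, min_count: int = 10, max_low_fraction: float = 0.90
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features below ``min_count`` in strictly more than ``max_low_fraction`` of samples."""
    if counts.scale_tag != "linear_counts":
        raise ValueError("count_filter expects a linear_counts matrix")
    if np.any(counts.values[counts.detected] < 0):
        raise ValueError("negative counts are invalid")
    low_frac = (counts.values < min_count).mean(axis=1)
    keep = np.flatnonzero(low_frac <= max_low_fraction)  # "more than" is strict
    report = FilterReport(counts.n_features, len(keep), "count_filter",
                          {"min_count": min_count, "max_low_fraction": max_low_fraction})
    log.info("%s", report)
    return counts.subset_features(keep), report


def pca_outlier_screen(
    m: ExpressionMatrix, n_components: int = 3, sd_multiplier: float = 3.0
) -> list[str]:
    """Flag samples far from the centroid in the first principal components.

    A sample is an outlier when its Euclidean distance from the score-space
    centroid exceeds mean + sd_multiplier * sd of all such distances.  This
    operationalizes a visual 3D-PCA screen; the multiplier is configurable.
    """
    from sklearn.decomposition import PCA

    if m.n_samples < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples")
    x = m.values.T  # samples x features
    if np.allclose(x.var(axis=0), 0):
        return []
    scores = PCA(n_components=n_components, random_state=0).fit_transform(x)
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    cutoff = dist.mean() + sd_multiplier * dist.std(ddof=1)
    flagged = [m.sample_ids[j] for j in np.flatnonzero(dist > cutoff)]
    log.info("pca_outlier_screen: flagged %d of %d samples (cutoff %.3f)",
             len(flagged), m.n_samples, cutoff)
    return flagged
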