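"""Expression-based miRNA->mRNA interaction detection.

Per-gene L1-penalized regression of the gene profile on its candidate miRNAs,
with a negative-regulation contract (positive coefficients are clipped to
zero after the fit) and a sample-label permutation p-value per retained edge.

The penalty is chosen by seeded 5-fold cross-validation; among penalties
whose CV error is within one standard error of the minimum, the sparsest
(largest) is taken, so ties break toward stronger sparsity.  The permutation
statistic is the univariate least-squares slope of gene on miR, which is
sign-consistent with the penalized coefficient in the single-candidate
OLS limit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from mirsubnet.io_core import ExpressionMatrix, PipelineConfig, get_logger

log = get_logger("interactions")


@dataclass
class InteractionRecord:
    mir_id: str
    gene_id: str
    coefficient: float  # log2 mRNA per log2 miR; retained edges are < 0
    perm_p: float
    subtype_context: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.coefficient >= 0:
            raise ValueError("retained interaction coefficient must be negative")
        if not (0.0 < self.perm_p <= 1.0):
            raise ValueError("perm_p must be in (0, 1]")


def build_candidate_pairs(
    mir_ids: Sequence[str], gene_ids: Sequence[str],
    prior_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> list[tuple[str, str]]:
    """Candidate (miR, gene) pairs: the prior list intersected with the
    available features, or the dense cross product when no prior is given."""
    mir_set, gene_set = set(mir_ids), set(gene_ids)
    if prior_pairs is None:
        return [(m, g) for m in mir_ids for g in gene_ids]
    kept, dropped = [], 0
    for m, g in prior_pairs:
        if m in mir_set and g in gene_set:
            kept.append((m, g))
        else:
            dropped += 1
    if dropped:
        log.warning("build_candidate_pairs: dropped %d pairs with unknown ids", dropped)
    return kept


def _seed_for(base_seed: int, tag: str) -> int:
    return (base_seed ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF


def fit_gene_lasso(
    gene_profile: np.ndarray,
    mir_profiles: np.ndarray,
    alphas: Optional[Sequence[float]] = None,
    rng_seed: int = 0,
    cv_folds: int = 5,
) -> np.ndarray:
    """L1-penalized coefficients of a gene on candidate miRs, positives clipped.

    ``mir_profiles`` is candidates x samples.  Profiles are standardized
    internally; returned coefficients are rescaled to log2-per-log2 slopes.
    """
    y = np.asarray(gene_profile, dtype=float)
    x = np.asarray(mir_profiles, dtype=float)
    if x.ndim != 2 or x.shape[1] != y.shape[0]:
        raise ValueError("mir_profiles must be candidates x samples matching gene profile")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    sd_y = y.std()
    sd_x = x.std(axis=1)
    if sd_y == 0 or np.any(sd_x == 0):
        # constant profiles carry no signal; coefficients are zero
        return np.zeros(x.shape[0])
    ys = (y - y.mean()) / sd_y
    xs = ((x - x.mean(axis=1, keepdims=True)) / sd_x[:, None]).T  # samples x cand

    if alphas is not None and len(alphas) == 1:
        model = Lasso(alpha=float(alphas[0]), max_iter=50_000)
        model.fit(xs, ys)
        coef_std = model.coef_
    else:
        cv = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=rng_seed)
        lcv = LassoCV(alphas=alphas if alphas is not None else 100,
                      cv=cv, max_iter=50_000)
        lcv.fit(xs, ys)
        # one-standard-error rule: sparsest penalty within 1 SE of the best
        mean_mse = lcv.mse_path_.mean(axis=1)
        se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
        best = int(np.argmin(mean_mse))
        ok = mean_mse <= mean_mse[best] + se[best]
        alpha = float(lcv.alphas_[ok].max())
        model = Lasso(alpha=alpha, max_iter=50_000)
        model.fit(xs, ys)
        coef_std = model.coef_

    coef = coef_std * sd_y / sd_x
    coef[coef > 0] = 0.0  # negative-regulation contract
    return coef


def permutation_significance(
    gene_profile: np.ndarray,
    mir_profile: np.ndarray,
    n_perm: int = 999,
    rng_seed: int = 0,
) -> float:
    """Permutation p of the gene-on-miR association.

    Statistic: |univariate least-squares slope|; the miR profile's sample
    labels are permuted.  p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    y = np.asarray(gene_profile, dtype=float)
    x = np.asarray(mir_profile, dtype=float)
    if y.shape != x.shape:
        raise ValueError("profiles must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = (xc ** 2).sum()
    if denom == 0 or (yc ** 2).sum() == 0:
        return 1.0
    observed = abs(xc @ yc / denom)
    if observed == 0:
        return 1.0
    rng = np.random.default_rng(rng_seed)
    n = len(x)
    perms = np.empty((n_perm, n), dtype=np.intp)
    for i in range(n_perm):
        perms[i] = rng.permutation(n)
    slopes = np.abs(xc[perms] @ yc / denom)
    exceed = int((slopes >= observed - 1e-15).sum())
    return (1 + exceed) / (n_perm + 1)


def infer_interactions(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    config: Optional[PipelineConfig] = None,
    de_context: Optional[Mapping[str, set[str]]] = None,
) -> list[InteractionRecord]:
    """Infer negative miR->gene interactions over candidate pairs.

    Genes are processed independently with per-gene seeds derived from the
    gene id, so results do not depend on scheduling or feature order.
    ``de_context`` maps gene id -> set of subtype labels where the gene is
    differentially expressed.
    """
    config = config or PipelineConfig()
    if list(mirna.sample_ids) != list(mrna.sample_ids):
        unmatched = sorted(set(mirna.sample_ids) ^ set(mrna.sample_ids))
        if unmatched:
            raise ValueError(f"sample mismatch between matrices: {unmatched[:10]}")
        # same set, different order: align mRNA columns to the miRNA order
        mrna = mrna.subset_samples(mirna.sample_ids)
    pairs = build_candidate_pairs(mirna.feature_ids, mrna.feature_ids, pairs)
    candidates_of_gene: dict[str, list[str]] = {}
    for m, g in pairs:
        candidates_of_gene.setdefault(g, []).append(m)

    mir_row = {m: i for i, m in enumerate(mirna.feature_ids)}
    gene_row = {g: i for i, g in enumerate(mrna.feature_ids)}
    records: list[InteractionRecord] = []
    for gene in sorted(candidates_of_gene):
        mirs = sorted(set(candidates_of_gene[gene]))
        y = mrna.values[gene_row[gene]]
        x = mirna.values[[mir_row[m] for m in mirs]]
        seed = _seed_for(config.rng_seed, gene)
        coef = fit_gene_lasso(y, x, rng_seed=seed)
        for ci in np.flatnonzero(coef < 0):
            mir = mirs[ci]
            p = permutation_significance(
                y, x[ci], n_perm=config.n_permutations,
                rng_seed=_seed_for(seed, mir),
            )
            if p < config.interaction_p_threshold:
                records.append(InteractionRecord(
                    mir_id=mir, gene_id=gene, coefficient=float(coef[ci]),
                    perm_p=p,
                    subtype_context=set(de_context.get(gene, set())) if de_context else set(),
                ))
    log.info("infer_interactions: %d significant edges from %d candidate pairs",
             len(records), len(pairs))
    return records


def score_recovery(
    records: Sequence[InteractionRecord], true_edges: set[tuple[str, str]]
) -> tuple[float, float]:
    """(precision, recall) of inferred edges against planted truth."""
    found = {(r.mir_id, r.gene_id) for r in records}
    if not found:
        return (1.0 if not true_edges else 0.0, 0.0 if true_edges else 1.0)
    tp = len(found & true_edges)
    precision = tp / len(found)
    recall = tp / len(true_edges) if true_edges else 1.0
    return precision, recall
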