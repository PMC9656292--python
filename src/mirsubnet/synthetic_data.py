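"""Synthetic paired miRNA/mRNA cohorts with planted ground truth.

Cohorts carry three planted tumor subtypes expressed as signed log2 shifts on
disjoint miRNA signature blocks, and planted negative miR->gene regulation
that is linear in log2 space.  Every downstream stage (subtyping, DE,
interaction inference, network analysis) can therefore be scored against a
known truth.

Planted signature geometry (three blocks):
  * block A — up in S2, down in S1
  * block B — down in S3
  * block C — up in S3
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from mirsubnet.io_core import ExpressionMatrix, SampleAnnotation
from mirsubnet.association_stats import ContingencyTable

SUBTYPE_LABELS = ("S1", "S2", "S3")


@dataclass
class SyntheticCohortSpec:
    """Parameters of the generated cohort.

    Defaults mirror the reference cohort geometry: 27/30/31 tumors in three
    subtypes, 19 normals, 176 miRNAs, 1722 genes.  Shift/effect magnitudes
    are free parameters (not estimates).
    """

    n_tumors_per_subtype: tuple[int, int, int] = (27, 30, 31)
    n_normals: int = 19
    n_mirs: int = 176
    n_genes: int = 1722
    block_shift: float = 1.0
    edge_effect: float = 0.8
    noise_sd: float = 0.5
    missing_rate: float = 0.02
    rng_seed: int = 0
    signature_block_size: int = 15
    n_edges: int = 30
    max_regulators_per_gene: int = 1
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_tumors_per_subtype) or self.n_normals < 2:
            raise ValueError("every sample group needs at least 2 samples")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.edge_effect <= 0:
            raise ValueError("edge_effect must be > 0 (positive beta = repression)")
        if 3 * self.signature_block_size > self.n_mirs:
            raise ValueError("signature blocks exceed the number of miRNAs")
        if self.max_regulators_per_gene < 1:
            raise ValueError("max_regulators_per_gene must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring.

    ``signature_blocks`` maps each subtype label to the signed log2 shifts of
    its signature miRNAs.  ``true_edges`` lists (miR, gene, beta) triples with
    beta > 0 meaning repression (gene = baseline - beta * miR + noise).
    """

    subtype_of_sample: dict[str, str]
    signature_blocks: dict[str, dict[str, float]]
    true_edges: list[tuple[str, str, float]]
    normal_samples: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for label, shifts in self.signature_blocks.items():
            if label not in SUBTYPE_LABELS:
                raise ValueError(f"unknown subtype label {label!r}")
            signs = {}
            for mir, shift in shifts.items():
                if mir in signs and np.sign(shift) != signs[mir]:
                    raise ValueError(f"conflicting shift signs for {mir} in {label}")
                signs[mir] = np.sign(shift)
        for mir, gene, beta in self.true_edges:
            if beta <= 0:
                raise ValueError("true edge beta must be > 0 (repression)")

    def edge_set(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.true_edges}

    def to_dict(self) -> dict:
        return {
            "subtype_of_sample": self.subtype_of_sample,
            "signature_blocks": self.signature_blocks,
            "true_edges": [[m, g, b] for m, g, b in self.true_edges],
            "normal_samples": sorted(self.normal_samples),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticTruth":
        return cls(
            subtype_of_sample=dict(doc["subtype_of_sample"]),
            signature_blocks={k: dict(v) for k, v in doc["signature_blocks"].items()},
            true_edges=[(m, g, float(b)) for m, g, b in doc["true_edges"]],
            normal_samples=set(doc["normal_samples"]),
        )


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Generate a paired miRNA/mRNA cohort under ``spec``.

    miR value = per-feature baseline + subtype block shift + N(0, noise_sd).
    Gene with incident edges = baseline - sum(beta * miR value) + noise;
    genes without edges = baseline + noise.  Normals carry no block shifts
    (regulatory edges still apply — they model biology, not tumor state).
    Detection flags are dropped uniformly at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_tumors = sum(spec.n_tumors_per_subtype)
    n_samples = n_tumors + spec.n_normals
    mir_ids = [f"miR-{i + 1:03d}" for i in range(spec.n_mirs)]
    gene_ids = [f"GENE{i + 1:04d}" for i in range(spec.n_genes)]
    tumor_ids = [f"T{i + 1:03d}" for i in range(n_tumors)]
    normal_ids = [f"N{i + 1:03d}" for i in range(spec.n_normals)]
    sample_ids = tumor_ids + normal_ids

    subtype_of_sample: dict[str, str] = {}
    pos = 0
    for label, n in zip(SUBTYPE_LABELS, spec.n_tumors_per_subtype):
        for s in tumor_ids[pos:pos + n]:
            subtype_of_sample[s] = label
        pos += n

    # disjoint signature blocks A/B/C
    b = spec.signature_block_size
    block_a = mir_ids[:b]
    block_b = mir_ids[b:2 * b]
    block_c = mir_ids[2 * b:3 * b]
    sh = spec.block_shift
    signature_blocks = {
        "S1": {m: -sh for m in block_a},
        "S2": {m: +sh for m in block_a},
        "S3": {**{m: -sh for m in block_b}, **{m: +sh for m in block_c}},
    }

    # planted repression edges on distinct genes, bounded regulators per gene
    if spec.n_edges > spec.n_mirs * spec.n_genes:
        raise ValueError("more edges requested than miR x gene pairs")
    max_edges = spec.n_genes * spec.max_regulators_per_gene
    if spec.n_edges > max_edges:
        raise ValueError(
            f"{spec.n_edges} edges exceed capacity "
            f"{max_edges} at {spec.max_regulators_per_gene} regulators/gene"
        )
    true_edges: list[tuple[str, str, float]] = []
    n_target_genes = int(np.ceil(spec.n_edges / spec.max_regulators_per_gene))
    target_genes = rng.choice(spec.n_genes, size=n_target_genes, replace=False)
    gi = 0
    regulators_of_gene: dict[int, set[int]] = {}
    while len(true_edges) < spec.n_edges:
        g = int(target_genes[gi % n_target_genes])
        gi += 1
        used = regulators_of_gene.setdefault(g, set())
        if len(used) >= spec.max_regulators_per_gene:
            continue
        m = int(rng.integers(spec.n_mirs))
        while m in used:
            m = int(rng.integers(spec.n_mirs))
        used.add(m)
        true_edges.append((mir_ids[m], gene_ids[g], float(spec.edge_effect)))

    # shift matrix: feature x sample
    mir_index = {m: i for i, m in enumerate(mir_ids)}
    shift = np.zeros((spec.n_mirs, n_samples))
    for j, s in enumerate(tumor_ids):
        for m, d in signature_blocks[subtype_of_sample[s]].items():
            shift[mir_index[m], j] = d

    mir_baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_mirs)
    mir_values = (
        mir_baseline[:, None] + shift
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_mirs, n_samples))
    )

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    gene_baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    gene_values = (
        gene_baseline[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    )
    for mir, gene, beta in true_edges:
        gene_values[gene_index[gene]] -= beta * mir_values[mir_index[mir]]

    mir_detected = rng.random((spec.n_mirs, n_samples)) >= spec.missing_rate
    gene_detected = rng.random((spec.n_genes, n_samples)) >= spec.missing_rate

    mirna = ExpressionMatrix(mir_ids, sample_ids, mir_values, mir_detected, "log2")
    mrna = ExpressionMatrix(gene_ids, sample_ids, gene_values, gene_detected, "log2")

    annots = [
        SampleAnnotation(sample_id=s, tissue="tumor", mrna_subtype=subtype_of_sample[s])
        for s in tumor_ids
    ] + [SampleAnnotation(sample_id=s, tissue="normal") for s in normal_ids]

    truth = SyntheticTruth(
        subtype_of_sample=subtype_of_sample,
        signature_blocks=signature_blocks,
        true_edges=true_edges,
        normal_samples=set(normal_ids),
    )
    return mirna, mrna, annots, truth


def generate_contingency(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    association_strength: float = 0.0,
    rng_seed: Optional[int] = None,
) -> ContingencyTable:
    """Cross-tabulate two label vectors, optionally tying them together.

    With ``association_strength`` p > 0, each position of ``labels_b`` is
    replaced, with probability p, by the image of the aligned ``labels_a``
    value under a fixed bijection-like mapping between the two level sets.
    Strength 0 cross-tabulates the vectors as given.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if not (0.0 <= association_strength <= 1.0):
        raise ValueError("association_strength must be in [0, 1]")
    labels_b = list(labels_b)
    if association_strength > 0.0:
        rng = np.random.default_rng(rng_seed)
        levels_a = sorted(set(labels_a))
        levels_b = sorted(set(labels_b))
        mapping = {a: levels_b[i % len(levels_b)] for i, a in enumerate(levels_a)}
        copy_mask = rng.random(len(labels_b)) < association_strength
        labels_b = [
            mapping[a] if c else b0
            for a, b0, c in zip(labels_a, labels_b, copy_mask)
        ]
    return ContingencyTable.from_labels(labels_a, labels_b)
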