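"""Candidate interaction ranking, seed-site matching and in-silico mutagenesis.

Evidence scores (WSP, LRS, number of supporting prediction algorithms) are
consumed as precomputed annotation columns and combined by an equal-weight
rank sum; already-validated pairs are dropped before ranking.  Seed-site
logic matches the exact reverse complement of miRNA positions 2-8 in a
3'UTR carried in its own 1-based coordinate frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.stats import rankdata

from mirsubnet.io_core import get_logger

log = get_logger("prioritize")

_DNA = set("ACGT")


@dataclass
class EvidenceAnnotation:
    mir_id: str
    gene_id: str
    wsp_score: float
    lrs_score: float
    n_prediction_algorithms: int
    validated_in_db: bool = False
    expression_correlation_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_prediction_algorithms <= 5):
            raise ValueError("n_prediction_algorithms must be in 0..5")
        if not (np.isfinite(self.wsp_score) and np.isfinite(self.lrs_score)):
            raise ValueError("scores must be finite")


def rank_candidates(
    edges: Sequence[tuple[str, str]],
    annotations: Mapping[tuple[str, str], EvidenceAnnotation],
    gene_closeness: Optional[Mapping[str, float]] = None,
) -> list[tuple[str, str]]:
    """Order edges by combined evidence, best first.

    Validated pairs are removed.  Remaining edges are ranked by the sum of
    their (ascending-value) ranks on WSP, LRS and algorithm count, ordered
    by descending rank sum; ties resolve by the gene's network closeness,
    then lexicographically.  Edges without an annotation row get neutral
    (zero) scores and a log line.
    """
    neutral = 0
    rows: list[tuple[str, str, float, float, int]] = []
    for mir, gene in edges:
        ann = annotations.get((mir, gene))
        if ann is None:
            neutral += 1
            rows.append((mir, gene, 0.0, 0.0, 0))
            continue
        if ann.validated_in_db:
            continue
        rows.append((mir, gene, ann.wsp_score, ann.lrs_score,
                     ann.n_prediction_algorithms))
    if neutral:
        log.info("rank_candidates: %d edges lacked annotation, scored neutral", neutral)
    if not rows:
        return []
    wsp = rankdata([r[2] for r in rows])
    lrs = rankdata([r[3] for r in rows])
    alg = rankdata([r[4] for r in rows])
    score = wsp + lrs + alg
    clo = gene_closeness or {}
    order = sorted(
        range(len(rows)),
        key=lambda i: (-score[i], -clo.get(rows[i][1], 0.0), rows[i][0], rows[i][1]),
    )
    return [(rows[i][0], rows[i][1]) for i in order]


# ---------------------------------------------------------------------------
# 3'UTR seed-site logic
# ---------------------------------------------------------------------------

@dataclass
class UTRSequence:
    gene_id: str
    sequence: str
    origin: int = 1  # 1-based coordinate of the first base

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(f"invalid bases in UTR {self.gene_id!r}: {sorted(bad)}")
        if len(self.sequence) < 7:
            raise ValueError("UTR sequence must be at least 7 nt")
        if self.origin < 1:
            raise ValueError("origin must be >= 1")

    @property
    def end(self) -> int:
        return self.origin + len(self.sequence) - 1

    def slice(self, start: int, stop: int) -> str:
        """Subsequence at 1-based inclusive coordinates in the UTR frame."""
        return self.sequence[start - self.origin:stop - self.origin + 1]


def seed_complement(mir_sequence: str) -> str:
    """DNA 7-mer site motif: reverse complement of miRNA positions 2-8.

    The mature miRNA is given 5'->3' over {A, C, G, U} (T accepted).
    """
    seq = mir_sequence.upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid bases in miRNA sequence: {sorted(bad)}")
    seed = seq[1:8]
    return str(Seq(seed).back_transcribe().reverse_complement())


def find_sites(utr: UTRSequence, motif: str) -> list[tuple[int, int]]:
    """All exact motif occurrences as 1-based inclusive (start, end) pairs
    in the UTR's own coordinate frame."""
    motif = motif.upper()
    if len(motif) != 7:
        raise ValueError("site motif must be a 7-mer")
    hits = []
    start = utr.sequence.find(motif)
    while start != -1:
        hits.append((utr.origin + start, utr.origin + start + 6))
        start = utr.sequence.find(motif, start + 1)
    return hits


_SUB_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


def apply_substitutions(utr: UTRSequence, subs: Sequence[str]) -> UTRSequence:
    """Apply single-base substitutions like ``G2226T`` (coordinates in the
    UTR frame).  The stated reference base must match the sequence — a
    mismatch is an error naming the position, guarding coordinate-frame bugs.
    """
    seq = list(utr.sequence)
    for sub in subs:
        m = _SUB_RE.match(sub.upper())
        if not m:
            raise ValueError(f"malformed substitution {sub!r} (expected e.g. G2226T)")
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        idx = pos - utr.origin
        if not (0 <= idx < len(seq)):
            raise ValueError(f"position {pos} outside UTR frame "
                             f"[{utr.origin}, {utr.end}]")
        if seq[idx] != ref:
            raise ValueError(
                f"reference mismatch at position {pos}: sequence has "
                f"{seq[idx]}, substitution names {ref}"
            )
        seq[idx] = alt
    return UTRSequence(utr.gene_id, "".join(seq), utr.origin)


_ORIGIN_RE = re.compile(r"origin=(\d+)")


def read_utr_fasta(path: str | Path) -> list[UTRSequence]:
    """Read UTRs from FASTA; an ``origin=N`` tag in the description sets the
    1-based coordinate of the first base (default 1)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _ORIGIN_RE.search(rec.description)
        origin = int(m.group(1)) if m else 1
        out.append(UTRSequence(rec.id, str(rec.seq), origin))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out
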