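"""Core I/O: expression matrices, sample annotations, run configuration.

Matrices are feature-major (rows = features, columns = samples), the
convention used by public expression repositories.  Undetected cells are
carried as an explicit boolean mask rather than NaN-only so that presence
filtering is decoupled from imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mirsubnet")

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def get_logger(stage: str) -> logging.Logger:
    """Return a child logger for a pipeline stage."""
    return logger.getChild(stage)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run configuration with defaults matching the published thresholds."""

    presence_fraction: float = 0.90
    de_p_threshold: float = 0.05
    fold_change_threshold: float = 1.5
    n_subtypes: int = 3
    top_central: int = 20
    clique_size_threshold: int = 3
    complex_size_threshold: int = 2
    min_count: int = 10
    max_low_fraction: float = 0.90
    interaction_p_threshold: float = 0.05
    rng_seed: int = 0
    # operational knobs (documented defaults, not published values)
    pca_sd_multiplier: float = 3.0
    de_use_adjusted_p: bool = True
    n_permutations: int = 999
    eagle_merge_threshold: float = 0.5
    community_mode: str = "projection"

    def __post_init__(self) -> None:
        for name in ("presence_fraction", "max_low_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("de_p_threshold", "interaction_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.fold_change_threshold <= 0:
            raise ValueError("fold_change_threshold must be > 0")
        for name in ("n_subtypes", "top_central", "clique_size_threshold",
                     "complex_size_threshold", "min_count", "n_permutations"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        if self.pca_sd_multiplier <= 0:
            raise ValueError("pca_sd_multiplier must be > 0")
        if self.community_mode not in ("projection", "bipartite"):
            raise ValueError("community_mode must be 'projection' or 'bipartite'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values with a detection mask.

    ``scale_tag`` is either ``"log2"`` (log2 intensities) or
    ``"linear_counts"`` (nonnegative counts).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    detected: np.ndarray
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.detected.shape != self.values.shape:
            raise ValueError("detected mask shape must equal values shape")
        for axis_name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicated {axis_name} id: {dupes[0]!r}")
        if not np.all(np.isfinite(self.values[self.detected])):
            raise ValueError("non-finite value in a detected cell")
        if self.scale_tag not in ("log2", "linear_counts"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.feature_ids), list(self.sample_ids),
            self.values.copy(), self.detected.copy(), self.scale_tag,
        )

    def subset_features(self, keep: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep, dtype=np.intp)
        return ExpressionMatrix(
            [self.feature_ids[i] for i in keep], list(self.sample_ids),
            self.values[keep], self.detected[keep], self.scale_tag,
        )

    def subset_samples(self, keep_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in keep_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        cols = [index[s] for s in keep_ids]
        return ExpressionMatrix(
            list(self.feature_ids), list(keep_ids),
            self.values[:, cols], self.detected[:, cols], self.scale_tag,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
        return df.mask(~self.detected)


def _duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dup = []
    for x in ids:
        if x in seen:
            dup.append(x)
        seen.add(x)
    return dup


def read_expression(path: str | Path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a tab-separated expression table.

    First column holds feature ids, the header row holds sample ids.  Empty
    cells and ``NA`` mark undetected measurements.  Duplicate ids and ragged
    rows are hard errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        n_cols = len(sample_ids)
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        masks: list[list[bool]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != n_cols + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row — expected {n_cols + 1} "
                    f"columns, found {len(cells)}"
                )
            feature_ids.append(cells[0])
            row, mask = [], []
            for cell in cells[1:]:
                if cell.strip() in _MISSING_TOKENS:
                    row.append(np.nan)
                    mask.append(False)
                else:
                    row.append(float(cell))
                    mask.append(True)
            rows.append(row)
            masks.append(mask)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionMatrix(
        feature_ids, sample_ids, np.array(rows, dtype=float),
        np.array(masks, dtype=bool), scale_tag,
    )


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; undetected cells become empty fields."""
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(m.sample_ids) + "\n")
        for i, fid in enumerate(m.feature_ids):
            cells = [
                format(m.values[i, j], ".10g") if m.detected[i, j] else ""
                for j in range(m.n_samples)
            ]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample annotation
# ---------------------------------------------------------------------------

@dataclass
class SampleAnnotation:
    """Per-sample clinical/technical annotation."""

    sample_id: str
    tissue: str  # tumor | normal | stroma | epithelium
    mrna_subtype: Optional[str] = None
    cms_label: Optional[str] = None
    msi: Optional[str] = None  # MSS | MSI
    braf: Optional[str] = None  # WT | Mut
    stroma_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tissue not in ("tumor", "normal", "stroma", "epithelium"):
            raise ValueError(f"invalid tissue {self.tissue!r}")
        if self.msi is not None and self.msi not in ("MSS", "MSI"):
            raise ValueError(f"invalid msi {self.msi!r}")
        if self.braf is not None and self.braf not in ("WT", "Mut"):
            raise ValueError(f"invalid braf {self.braf!r}")
        if self.stroma_percent is not None and not (0 <= self.stroma_percent <= 100):
            raise ValueError("stroma_percent must be within [0, 100]")


_ANNOT_COLUMNS = ["sample_id", "tissue", "mrna_subtype", "cms_label",
                  "msi", "braf", "stroma_percent"]


def annotations_to_frame(annots: Sequence[SampleAnnotation]) -> pd.DataFrame:
    ids = [a.sample_id for a in annots]
    dupes = _duplicates(ids)
    if dupes:
        raise ValueError(f"duplicated sample_id in annotation: {dupes[0]!r}")
    return pd.DataFrame(
        [[getattr(a, c) for c in _ANNOT_COLUMNS] for a in annots],
        columns=_ANNOT_COLUMNS,
    )


def write_annotation(annots: Sequence[SampleAnnotation], path: str | Path) -> None:
    annotations_to_frame(annots).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotation(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"],
                     keep_default_na=True)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in _ANNOT_COLUMNS:
            v = row.get(c)
            kwargs[c] = None if pd.isna(v) else v
        out.append(SampleAnnotation(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(network, path: str | Path, dialect: str = "SIF") -> None:
    """Export a regulatory network in a Cytoscape-loadable dialect.

    SIF lines read ``<miR> regulates <gene>``.  GML carries a ``kind``
    attribute (miR vs gene) and any centrality attributes already attached
    to the graph nodes.
    """
    import networkx as nx

    graph = network.graph if hasattr(network, "graph") else network
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot export an empty network")
    if dialect.upper() == "SIF":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                if graph.nodes[u].get("kind") == "miR":
                    mir, gene = u, v
                else:
                    mir, gene = v, u
                fh.write(f"{mir}\tregulates\t{gene}\n")
    elif dialect.upper() == "GML":
        nx.write_gml(graph, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use SIF or GML")


def read_network_gml(path: str | Path):
    import networkx as nx

    return nx.read_gml(path)
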