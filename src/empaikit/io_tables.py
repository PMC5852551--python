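"""Typed containers and TSV readers/writers for the abundance pipeline.

All tables are plain tab-separated UTF-8 text with one header line and a
decimal point (never a comma), so outputs are diffable and portable between
runs.  Downstream modules never touch raw files; they operate on the
validated containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinRecord",
    "AbundanceMatrix",
    "PipelineConfig",
    "read_abundance_table",
    "write_abundance_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_config",
]


@dataclass(frozen=True)
class ProteinRecord:
    """Annotation for one protein-coding gene.

    ``genome_order`` is the 1-based rank of the gene along its contig; the
    silent-island scan needs only this adjacency, not base-pair coordinates.
    ``arcog_id`` is an orthologous-group identifier (shared membership within
    one genome defines a paralogous family); ``category`` is a one-letter
    functional class code.
    """

    locus_tag: str
    contig: str
    genome_order: int
    arcog_id: Optional[str] = None
    category: Optional[str] = None
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.genome_order < 1:
            raise ValueError(
                f"genome_order must be a positive rank, got {self.genome_order} "
                f"for {self.locus_tag}"
            )


class AbundanceMatrix:
    """Raw emPAI values, proteins x conditions, with one baseline condition.

    A value of exactly 0 means "not detected"; all values must be
    non-negative.  Row index holds locus tags (unique), columns hold
    condition labels in the order given by the source table.
    """

    def __init__(self, data: pd.DataFrame, baseline: str):
        data = data.astype(float)
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate locus tag: {dup!r}")
        if (data.values < 0).any():
            bad = data.index[(data.values < 0).any(axis=1)][0]
            raise ValueError(f"negative emPAI value for locus {bad!r}")
        if baseline not in data.columns:
            raise ValueError(
                f"baseline condition {baseline!r} not among columns "
                f"{list(data.columns)}"
            )
        self.data = data
        self.baseline = baseline

    @property
    def conditions(self) -> list:
        return list(self.data.columns)

    @property
    def loci(self) -> list:
        return list(self.data.index)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AbundanceMatrix)
            and self.baseline == other.baseline
            and self.data.equals(other.data)
        )

    def __repr__(self) -> str:
        return (
            f"AbundanceMatrix({self.n_proteins} proteins x "
            f"{len(self.conditions)} conditions, baseline={self.baseline!r})"
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the analysis.

    scale_count
        Number of distinct proteins P the per-condition nemPAI sums are
        rescaled to (e.g. 1529 for a small archaeal proteome).  ``None`` means "use the
        row count of the matrix".
    pseudo_abundance
        Artificial low nemPAI substituted for zeros at the log step only
        (default 0.001, below any real nemPAI).
    threshold_tau
        Significance threshold in decimal log10 units (default 0.5, i.e. a
        linear factor of 10**0.5 ~ 3.16).
    correlation_cutoff, null_pairs
        Paralog-analysis tail cutoff on Pearson r and the number of random
        singleton pairs drawn for the null.
    reference_set
        Locus tags of the stoichiometric reference proteins (e.g. the 25
        ribosomal-superoperon proteins) used for noise calibration.
    min_silent_run
        Minimum number of consecutive undetected genes forming a silent
        island.
    """

    scale_count: Optional[int] = None
    pseudo_abundance: float = 1e-3
    threshold_tau: float = 0.5
    correlation_cutoff: float = 0.8
    null_pairs: int = 10_000
    rng_seed: int = 0
    reference_set: tuple = field(default_factory=tuple)
    min_silent_run: int = 5

    def __post_init__(self) -> None:
        if self.pseudo_abundance <= 0:
            raise ValueError("pseudo_abundance must be positive")
        if self.threshold_tau <= 0:
            raise ValueError("threshold_tau must be positive")
        if not (0 < self.correlation_cutoff <= 1):
            raise ValueError("correlation_cutoff must lie in (0, 1]")
        if self.null_pairs < 1:
            raise ValueError("null_pairs must be positive")
        if self.min_silent_run < 1:
            raise ValueError("min_silent_run must be positive")
        object.__setattr__(self, "reference_set", tuple(self.reference_set))

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers


def read_abundance_table(path, baseline: str) -> AbundanceMatrix:
    """Read a locus x condition emPAI table (TSV, first column locus tags).

    Missing/empty cells are "not detected" and become 0.  Condition order is
    taken from the header.  Duplicate locus tags, negative values and an
    unknown baseline are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip")
    df = df.fillna(0.0)
    return AbundanceMatrix(df, baseline=baseline)


def write_abundance_table(m: AbundanceMatrix, path) -> None:
    out = m.data.copy()
    out.index.name = out.index.name or "locus_tag"
    out.to_csv(path, sep="\t")


_ANNOT_COLS = ["locus_tag", "contig", "genome_order", "arcog_id", "category", "annotation"]


def read_annotation_table(path) -> list:
    """Read the protein annotation TSV; records come back sorted by
    (contig, genome_order).  Duplicate genome_order within a contig is an
    error."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOT_COLS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table lacks required columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ProteinRecord(
                locus_tag=row.locus_tag,
                contig=row.contig,
                genome_order=int(row.genome_order),
                arcog_id=getattr(row, "arcog_id", "") or None,
                category=getattr(row, "category", "") or None,
                annotation=getattr(row, "annotation", ""),
            )
        )
    _check_unique_orders(records)
    tags = [r.locus_tag for r in records]
    if len(set(tags)) != len(tags):
        dup = next(t for t in tags if tags.count(t) > 1)
        raise ValueError(f"duplicate locus tag in annotation table: {dup!r}")
    records.sort(key=lambda r: (r.contig, r.genome_order))
    return records


def _check_unique_orders(records: Sequence[ProteinRecord]) -> None:
    seen = {}
    for r in records:
        key = (r.contig, r.genome_order)
        if key in seen:
            raise ValueError(
                f"genome_order {r.genome_order} duplicated on contig "
                f"{r.contig!r} ({seen[key]} vs {r.locus_tag})"
            )
        seen[key] = r.locus_tag


def write_annotation_table(records: Sequence[ProteinRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.locus_tag, r.contig, r.genome_order, r.arcog_id or "", r.category or "", r.annotation)
            for r in records
        ],
        columns=_ANNOT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_config(path) -> PipelineConfig:
    """Read a flat ``key = value`` config file (``#`` comments allowed).

    ``reference_set`` may be a comma-separated locus list or a path to a
    one-column text file of locus tags (resolved relative to the config)."""
    kwargs = {}
    base = Path(path).parent
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key in ("scale_count", "null_pairs", "rng_seed", "min_silent_run"):
            kwargs[key] = int(value)
        elif key in ("pseudo_abundance", "threshold_tau", "correlation_cutoff"):
            kwargs[key] = float(value)
        elif key == "reference_set":
            if "," in value or not (base / value).exists():
                kwargs[key] = tuple(s.strip() for s in value.split(",") if s.strip())
            else:
                kwargs[key] = tuple(
                    (base / value).read_text().split()
                )
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return PipelineConfig(**kwargs)
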