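"""Per-gene GC reporting and genome-wide GC-percentile anomaly scoring.

A gene acquired from a donor with a different base composition stands out
against the distribution of GC content over all genes of its host. The
headline statistic is the fraction of other genes whose GC content equals
or exceeds that of a focal gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .seq_core import Genome, GeneFeature, gc_fraction

logger = logging.getLogger(__name__)


@dataclass
class GeneGCRecord:
    feature_id: str
    start: int
    end: int
    strand: str
    length: int
    gene_gc: float  # full-precision fraction in [0, 1]
    genome_gc: float

    @property
    def position(self) -> str:
        return f"{self.start}..{self.end}"

    @property
    def gene_gc_percent(self) -> float:
        """Display value: percent rounded half-up to 1 decimal."""
        return _round1(self.gene_gc * 100)

    @property
    def genome_gc_percent(self) -> float:
        return _round1(self.genome_gc * 100)


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gene_gc_table(genome: Genome, features: list[GeneFeature]) -> list[GeneGCRecord]:
    """One GC record per feature plus the genome-wide GC.

    GC is strand-invariant, so each gene's GC is computed on the + strand
    span. Features outside the genome raise a validation error naming the
    feature; comparisons downstream always use the full-precision values,
    rounding is for display only.
    """
    n = len(genome)
    genome_gc = gc_fraction(genome.sequence)
    records = []
    for f in features:
        if f.end > n:
            raise ValueError(
                f"feature {f.feature_id!r} span {f.start}..{f.end} exceeds "
                f"genome {genome.id!r} length {n}"
            )
        records.append(
            GeneGCRecord(
                feature_id=f.feature_id,
                start=f.start,
                end=f.end,
                strand=f.strand,
                length=f.length,
                gene_gc=gc_fraction(genome.sequence[f.start - 1 : f.end]),
                genome_gc=genome_gc,
            )
        )
    return records


def gc_percentile(
    records: list[GeneGCRecord], focal_feature_id: str, include_focal: bool = False
) -> float:
    """Fraction of genes with GC >= the focal gene's GC.

    By default the focal gene is excluded from the comparison set ("how
    many *other* genes are at least this GC-rich"); ``include_focal=True``
    switches to counting it. Requires at least two records.
    """
    focal = [r for r in records if r.feature_id == focal_feature_id]
    if not focal:
        raise KeyError(f"focal feature {focal_feature_id!r} not in records")
    if len(records) < 2:
        raise ValueError("gc_percentile needs at least 2 gene records")
    focal_gc = focal[0].gene_gc
    others = records if include_focal else [
        r for r in records if r.feature_id != focal_feature_id
    ]
    return sum(1 for r in others if r.gene_gc >= focal_gc) / len(others)


def to_dataframe(records: list[GeneGCRecord]) -> pd.DataFrame:
    """Report table mirroring the standard gene-GC layout (1-decimal percents)."""
    return pd.DataFrame(
        {
            "gene": [r.feature_id for r in records],
            "position": [r.position for r in records],
            "strand": [r.strand for r in records],
            "length_bp": [r.length for r in records],
            "gc_percent": [r.gene_gc_percent for r in records],
            "genome_gc_percent": [r.genome_gc_percent for r in records],
        }
    )


def write_tsv(records: list[GeneGCRecord], path: str | Path) -> None:
    to_dataframe(records).to_csv(path, sep="\t", index=False)


def write_json(records: list[GeneGCRecord], path: str | Path) -> None:
    """Full-precision JSON variant of the report."""
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in records], fh, indent=1)
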