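"""Sequence and annotation data model shared by all analysis stages.

Coordinates on all public interfaces are 1-based and inclusive, matching
the convention of bacterial genome annotation tables (``start..end``).
Sequences are normalized to upper case over the IUPAC nucleotide alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_NT = set("ACGTNRYSWKMBDHV")

#: IUPAC code -> set of unambiguous bases it stands for
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class SequenceAlphabetError(ValueError):
    """Sequence contains characters outside the IUPAC nucleotide alphabet."""


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class RegionBoundsError(ValueError):
    """Requested region lies outside the genome and clamping is disabled."""


class UndefinedGCError(ValueError):
    """GC content is undefined (no unambiguous A/C/G/T bases)."""


@dataclass
class Genome:
    """A nucleotide sequence with an identifier.

    Parameters
    ----------
    id:
        Record label (first whitespace-delimited token of a FASTA header).
    sequence:
        Upper-case IUPAC nucleotide string.
    topology:
        ``linear`` or ``circular``; circular genomes are treated as linear
        starting at position 1 (regions may not wrap the origin).
    """

    id: str
    sequence: str
    topology: Literal["linear", "circular"] = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: sequence is empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise SequenceAlphabetError(
                f"genome {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """An annotated gene span, 1-based inclusive."""

    feature_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.feature_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"feature {self.feature_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Region:
    """A genomic interval on a named genome, 1-based inclusive."""

    genome_id: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    #: set when the requested span was clamped to the contig bounds
    clamped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def reverse_complement(sequence: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return sequence.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[Genome]:
    """Read a (multi-)FASTA file into a list of :class:`Genome`.

    Raises :class:`FastaParseError` when the file does not start with a
    header line or contains an empty record, naming the line number.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1: expected '>' FASTA header")
    genomes: list[Genome] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} is empty")
        genomes.append(Genome(id=rec.id, sequence=seq, description=rec.description))
    if not genomes:
        raise FastaParseError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            header = g.description if g.description and g.description != g.id else g.id
            fh.write(f">{header}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


_GFF3_STRANDS = {"+", "-"}


def read_features(path: str | Path, format: Literal["gff3", "tsv"] = "tsv") -> list[GeneFeature]:
    """Read gene features from GFF3 or a 4-column TSV (id, start, end, strand).

    Coordinates are taken verbatim (both formats are 1-based inclusive).
    A GFF3 strand of ``.`` or ``?`` is rejected: every analysis here is
    strand-aware.
    """
    path = Path(path)
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if format == "gff3":
                if len(cols) < 9:
                    raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
                start, end, strand = int(cols[3]), int(cols[4]), cols[6]
                if strand not in _GFF3_STRANDS:
                    raise ValueError(
                        f"{path}: line {lineno}: unsupported strand {strand!r}"
                    )
                attrs = dict(
                    kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
                )
                fid = attrs.get("ID") or attrs.get("Name") or f"feature_{lineno}"
                product = attrs.get("product")
            else:
                cols = re.split(r"\s+", line.strip())
                if len(cols) < 4:
                    raise ValueError(
                        f"{path}: line {lineno}: expected 4 columns (id start end strand)"
                    )
                fid, start, end, strand = cols[0], int(cols[1]), int(cols[2]), cols[3]
                product = cols[4] if len(cols) > 4 else None
            if end < start:
                raise ValueError(f"{path}: line {lineno}: end {end} < start {start}")
            feats.append(GeneFeature(fid, start, end, strand, product))  # type: ignore[arg-type]
    return feats


def extract_region(genome: Genome, region: Region, clamp: bool = True) -> tuple[str, Region]:
    """Extract the subsequence of ``region`` from ``genome``.

    Returns ``(sequence, effective_region)``. On the minus strand the
    reverse complement is returned. Spans reaching past the contig ends are
    clamped to ``[1, N]`` and the clamp recorded on the returned region;
    with ``clamp=False`` such spans raise :class:`RegionBoundsError`.
    """
    n = len(genome)
    start, end = region.start, region.end
    clamped = False
    if start < 1 or end > n:
        if not clamp:
            raise RegionBoundsError(
                f"region {start}..{end} outside genome {genome.id!r} (length {n})"
            )
        start, end = max(start, 1), min(end, n)
        clamped = True
    eff = Region(genome.id, start, end, region.strand, clamped=clamped)
    seq = genome.sequence[start - 1 : end]
    if region.strand == "-":
        seq = reverse_complement(seq)
    return seq, eff


def gc_fraction(sequence: str) -> float:
    """GC fraction over unambiguous bases: (G+C) / (A+C+G+T).

    Ambiguity codes (including N) are excluded from numerator and
    denominator, so the value is invariant under masking. Raises
    :class:`UndefinedGCError` when no unambiguous base remains.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise UndefinedGCError("sequence has no unambiguous A/C/G/T bases")
    return gc / (gc + at)


def translate(sequence: str) -> str:
    """Standard-code translation (bacterial table 11 start codons not applied)."""
    return str(Seq(sequence).translate())
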