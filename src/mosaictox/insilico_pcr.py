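"""In-silico PCR: primer binding-site search and amplicon prediction.

Pure sequence matching — IUPAC-aware mismatch counting with an exact
3'-terminal clamp — with no melting-temperature or dimer modelling. An
amplicon spans from the 5' end of the forward primer's site to the
forward-strand coordinate of the reverse primer's 5' end, inclusive, so
both primer footprints are inside the reported interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .seq_core import Genome, IUPAC_SETS, reverse_complement


@dataclass
class Primer:
    name: str
    sequence: str  # 5'->3', IUPAC codes allowed

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 10:
            raise ValueError(f"primer {self.name!r}: length must be >= 10")
        bad = set(self.sequence) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name!r}: invalid characters {sorted(bad)}")


#: screening primer pairs targeting the fitD/mcf toxin genes
FIT1F = Primer("fit1f", "TGGCTTTTATGTCCAAGGAC")
FIT1R = Primer("fit1r", "TGGTTGGCGAAGTACTGCTC")
FIT2F = Primer("fit2f", "CTGACCACGTTCGACGCCGAGCAATG")
FIT2R = Primer("fit2r", "TAACGTCCCACCGCCTTGGCATCTTCG")


@dataclass
class PrimerSite:
    position: int  # 1-based forward-strand coordinate of the site's left end
    strand: str  # "+" if the primer matches the forward strand
    mismatches: int


@dataclass
class AmpliconHit:
    template_id: str
    start: int
    end: int
    mismatches_fwd: int
    mismatches_rev: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _bases_compatible(primer_base: str, template_base: str) -> bool:
    """True when the IUPAC base sets intersect."""
    p = IUPAC_SETS.get(primer_base)
    t = IUPAC_SETS.get(template_base)
    if p is None or t is None:
        return False
    return bool(p & t)


def _scan_strand(
    template: str, primer: str, max_mismatch: int, three_prime_exact: int
) -> list[tuple[int, int]]:
    """(0-based position, mismatches) of acceptable sites on one strand.

    The primer's 3' end is its right end here (primer given 5'->3' matching
    this strand left to right).
    """
    m = len(primer)
    hits = []
    clamp_start = m - three_prime_exact
    for i in range(len(template) - m + 1):
        window = template[i : i + m]
        mm = 0
        ok = True
        for j in range(m - 1, -1, -1):  # scan from the 3' end: fail fast on clamp
            if not _bases_compatible(primer[j], window[j]):
                if j >= clamp_start:
                    ok = False
                    break
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            hits.append((i, mm))
    return hits


def find_sites(
    template: Genome | str,
    primer: Primer,
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
) -> list[PrimerSite]:
    """All binding sites of a primer on both strands of a template.

    Positions are 1-based forward-strand coordinates of the leftmost base
    of the site. Total mismatches must not exceed ``max_mismatch`` and the
    ``three_prime_exact`` 3'-terminal primer bases must match exactly.
    """
    seq = template.sequence if isinstance(template, Genome) else template.upper()
    n = len(seq)
    sites = [
        PrimerSite(i + 1, "+", mm)
        for i, mm in _scan_strand(seq, primer.sequence, max_mismatch, three_prime_exact)
    ]
    rc = reverse_complement(seq)
    for i, mm in _scan_strand(rc, primer.sequence, max_mismatch, three_prime_exact):
        # leftmost forward-strand base of the site
        sites.append(PrimerSite(n - (i + len(primer.sequence)) + 1, "-", mm))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def predict_amplicons(
    template: Genome | str,
    fwd: Primer,
    rev: Primer,
    size_range: tuple[int, int] = (50, 10000),
    max_mismatch: int = 0,
    three_prime_exact: int = 3,
    template_id: str | None = None,
) -> list[AmpliconHit]:
    """Pair opposing primer sites into amplicons.

    Amplification is orientation-agnostic: either primer may provide the
    plus-strand site as long as the other binds the minus strand
    downstream of it (primers facing each other). The amplicon interval
    runs from the left site's left end to the right site's right end (the
    minus-strand primer's 5' base on the forward strand), filtered to
    ``size_range`` and sorted by start.
    """
    if isinstance(template, Genome):
        tid = template_id or template.id
    else:
        tid = template_id or "template"
    fwd_sites = find_sites(template, fwd, max_mismatch, three_prime_exact)
    rev_sites = find_sites(template, rev, max_mismatch, three_prime_exact)
    lo, hi = size_range
    hits = []
    pairings = [
        (fwd, rev, fwd_sites, rev_sites),  # fwd on +, rev on -
        (rev, fwd, rev_sites, fwd_sites),  # rev on +, fwd on -
    ]
    for left_primer, right_primer, left_sites, right_sites in pairings:
        for f in (s for s in left_sites if s.strand == "+"):
            for r in (s for s in right_sites if s.strand == "-"):
                end = r.position + len(right_primer.sequence) - 1
                if end <= f.position:
                    continue
                length = end - f.position + 1
                if lo <= length <= hi:
                    hits.append(
                        AmpliconHit(
                            template_id=tid,
                            start=f.position,
                            end=end,
                            mismatches_fwd=f.mismatches,
                            mismatches_rev=r.mismatches,
                        )
                    )
    unique = {(h.start, h.end): h for h in hits}
    return sorted(unique.values(), key=lambda h: (h.start, h.end))


def read_primers_tsv(path: str | Path) -> list[Primer]:
    primers = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, seq = line.split("\t")[:2]
            primers.append(Primer(name, seq))
    return primers


def write_hits_tsv(hits: list[AmpliconHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("template\tstart\tend\tlength\tmismatches_fwd\tmismatches_rev\n")
        for h in hits:
            fh.write(
                f"{h.template_id}\t{h.start}\t{h.end}\t{h.length}\t"
                f"{h.mismatches_fwd}\t{h.mismatches_rev}\n"
            )


def write_hits_bed(hits: list[AmpliconHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, h in enumerate(hits, 1):
            fh.write(f"{h.template_id}\t{h.start - 1}\t{h.end}\tamplicon_{i}\n")
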