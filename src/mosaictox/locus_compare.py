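"""Pairwise locus comparison: anchored alignment and windowed identity tracks.

Homologous toxin loci (toxin gene plus flanking DNA) are aligned with a
seed-chain-extend anchored global aligner — exact-match k-mer anchors,
chained co-linearly for maximum anchored coverage, with the gaps between
anchors closed by affine-gap global alignment — and percent identity is
then reported in non-overlapping windows on reference coordinates. A
mosaic locus appears as abrupt transitions between high-identity and
unalignable windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align

from .seq_core import Genome, GeneFeature, Region, extract_region

logger = logging.getLogger(__name__)


@dataclass
class LocusParams:
    flank: int = 25000
    window: int = 100
    high_conservation: float = 70.0
    plot_floor: float = 50.0

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError("window must be >= 10")
        if not (0 <= self.plot_floor < self.high_conservation <= 100):
            raise ValueError("require 0 <= plot_floor < high_conservation <= 100")


@dataclass
class AlignScoring:
    """Match/mismatch with affine gaps (open charged in addition to extend)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


@dataclass
class Anchor:
    ref_pos: int  # 1-based start on ref
    qry_pos: int
    length: int


@dataclass
class PairwiseAlignment:
    ref_id: str
    qry_id: str
    ref_aln: str
    qry_aln: str
    #: per-column flag: False inside unalignable blocks emitted as gap filler
    aligned: np.ndarray
    anchors: list[Anchor] = field(default_factory=list)
    fully_unaligned: bool = False

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.qry_aln):
            raise ValueError("alignment rows differ in length")

    @property
    def ref_seq(self) -> str:
        return self.ref_aln.replace("-", "")

    @property
    def qry_seq(self) -> str:
        return self.qry_aln.replace("-", "")


@dataclass
class SimilarityTrack:
    ref_id: str
    window_starts: np.ndarray  # 1-based ref coordinates, stride = window
    window_ends: np.ndarray
    identity: np.ndarray  # percent
    classes: list[str]  # high | low | unaligned
    window: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ref_start\tref_end\tidentity\tclass\n")
            for s, e, i, c in zip(self.window_starts, self.window_ends, self.identity, self.classes):
                fh.write(f"{s}\t{e}\t{i:.2f}\t{c}\n")

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write('track type=bedGraph name="percent_identity"\n')
            for s, e, i in zip(self.window_starts, self.window_ends, self.identity):
                fh.write(f"{self.ref_id}\t{s - 1}\t{e}\t{i:.2f}\n")


@dataclass
class LabelledSegment:
    start: int
    end: int
    label: str
    mean_identity: float


def extract_toxin_locus(
    genome: Genome, toxin_feature: GeneFeature, params: LocusParams | None = None
) -> tuple[Region, str]:
    """Toxin gene plus symmetric flanks, oriented so the toxin reads left to right.

    The region spans ``[gene_start - flank, gene_end + flank]`` clamped to
    the contig; for a minus-strand toxin the same genomic span is returned
    reverse-complemented.
    """
    params = params or LocusParams()
    want = Region(
        genome.id,
        max(toxin_feature.start - params.flank, 1),
        toxin_feature.end + params.flank,
        toxin_feature.strand,
    )
    if toxin_feature.start - params.flank < 1:
        want.clamped = True
    seq, eff = extract_region(genome, want)
    eff.clamped = eff.clamped or want.clamped
    if eff.clamped:
        logger.info(
            "locus around %s clamped to contig bounds: %d..%d",
            toxin_feature.feature_id, eff.start, eff.end,
        )
    return eff, seq


# ---------------------------------------------------------------------------
# anchor finding and chaining


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    """k-mer -> 0-based position, for k-mers occurring exactly once."""
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def _find_anchors(ref: str, qry: str, k: int) -> list[Anchor]:
    """Matches of k-mers unique in both sequences, merged along diagonals."""
    ref_pos = _unique_kmer_positions(ref, k)
    qry_pos = _unique_kmer_positions(qry, k)
    hits = sorted(
        (rp, qry_pos[kmer]) for kmer, rp in ref_pos.items() if kmer in qry_pos
    )
    anchors: list[Anchor] = []
    for rp, qp in hits:
        if anchors:
            last = anchors[-1]
            if (
                rp - (last.ref_pos - 1) == qp - (last.qry_pos - 1)
                and rp <= last.ref_pos - 1 + last.length
            ):
                last.length = rp + k - (last.ref_pos - 1)
                continue
        anchors.append(Anchor(rp + 1, qp + 1, k))
    return anchors


class _FenwickMax:
    """Prefix-maximum Fenwick tree over 1..n storing (value, payload)."""

    def __init__(self, n: int) -> None:
        self.n = n
        self.val = [0.0] * (n + 1)
        self.arg = [-1] * (n + 1)

    def update(self, i: int, value: float, payload: int) -> None:
        while i <= self.n:
            if value > self.val[i]:
                self.val[i], self.arg[i] = value, payload
            i += i & (-i)

    def query(self, i: int) -> tuple[float, int]:
        best, arg = 0.0, -1
        while i > 0:
            if self.val[i] > best:
                best, arg = self.val[i], self.arg[i]
            i -= i & (-i)
        return best, arg


def _chain_anchors(anchors: list[Anchor]) -> list[Anchor]:
    """Highest-coverage co-linear non-overlapping chain (LIS on both axes)."""
    if not anchors:
        return []
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].ref_pos, anchors[i].qry_pos))
    qry_ends = sorted({anchors[i].qry_pos + anchors[i].length - 1 for i in order})
    rank = {v: j + 1 for j, v in enumerate(qry_ends)}
    fen = _FenwickMax(len(qry_ends))
    by_ref_end = sorted(order, key=lambda i: anchors[i].ref_pos + anchors[i].length - 1)
    dp = [0.0] * len(anchors)
    parent = [-1] * len(anchors)
    ptr = 0
    for i in order:
        a = anchors[i]
        while ptr < len(by_ref_end):
            j = by_ref_end[ptr]
            b = anchors[j]
            if b.ref_pos + b.length - 1 < a.ref_pos:
                fen.update(rank[b.qry_pos + b.length - 1], dp[j], j)
                ptr += 1
            else:
                break
        # best predecessor ending strictly left of this anchor on both axes
        import bisect

        r = bisect.bisect_left(qry_ends, a.qry_pos)
        best, arg = fen.query(r) if r > 0 else (0.0, -1)
        dp[i] = best + a.length
        parent[i] = arg
    end = int(np.argmax(dp))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = parent[end]
    return chain[::-1]


# ---------------------------------------------------------------------------
# gap filling


def _make_aligner(s: AlignScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = s.match
    al.mismatch_score = s.mismatch
    # Biopython charges open on the first gap column; our convention charges
    # gap_open in addition to the first extend.
    al.open_gap_score = s.gap_open + s.gap_extend
    al.extend_gap_score = s.gap_extend
    return al


def _global_align(a: str, b: str, aligner: Align.PairwiseAligner) -> tuple[str, str]:
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def anchor_align(
    ref_seq: str,
    qry_seq: str,
    k: int = 12,
    max_gap: int = 2000,
    scoring: AlignScoring | None = None,
    ref_id: str = "ref",
    qry_id: str = "qry",
) -> PairwiseAlignment:
    """Anchored global alignment of two loci.

    Unique exact-match k-mer anchors are chained co-linearly; inter-anchor
    gaps up to ``max_gap`` are closed by affine-gap global alignment, and
    larger gaps are emitted unaligned (each side against gap filler, with
    the per-column ``aligned`` mask cleared). With no anchors at all, short
    inputs (within ``max_gap``) fall back to plain global alignment and
    long ones come back fully unaligned and flagged.
    """
    scoring = scoring or AlignScoring()
    aligner = _make_aligner(scoring)
    ref_seq, qry_seq = ref_seq.upper(), qry_seq.upper()
    chain = _chain_anchors(_find_anchors(ref_seq, qry_seq, k))

    ref_parts: list[str] = []
    qry_parts: list[str] = []
    mask_parts: list[np.ndarray] = []

    def emit(r: str, q: str, aligned: bool) -> None:
        ref_parts.append(r)
        qry_parts.append(q)
        mask_parts.append(np.full(len(r), aligned, dtype=bool))

    def fill(r: str, q: str) -> None:
        if not r and not q:
            return
        if max(len(r), len(q)) <= max_gap:
            a, b = _global_align(r, q, aligner)
            emit(a, b, True)
        else:
            if r:
                emit(r, "-" * len(r), False)
            if q:
                emit("-" * len(q), q, False)

    rpos = qpos = 0  # 0-based consumed prefix lengths
    for a in chain:
        fill(ref_seq[rpos : a.ref_pos - 1], qry_seq[qpos : a.qry_pos - 1])
        emit(
            ref_seq[a.ref_pos - 1 : a.ref_pos - 1 + a.length],
            qry_seq[a.qry_pos - 1 : a.qry_pos - 1 + a.length],
            True,
        )
        rpos, qpos = a.ref_pos - 1 + a.length, a.qry_pos - 1 + a.length
    fill(ref_seq[rpos:], qry_seq[qpos:])

    ref_aln = "".join(ref_parts)
    qry_aln = "".join(qry_parts)
    mask = np.concatenate(mask_parts) if mask_parts else np.zeros(0, dtype=bool)
    fully_unaligned = not chain and bool(mask.size) and not mask.any()
    if fully_unaligned:
        logger.warning("no anchors found between %s and %s", ref_id, qry_id)
    return PairwiseAlignment(
        ref_id=ref_id,
        qry_id=qry_id,
        ref_aln=ref_aln,
        qry_aln=qry_aln,
        aligned=mask,
        anchors=chain,
        fully_unaligned=fully_unaligned,
    )


def alignment_score(aln: PairwiseAlignment, scoring: AlignScoring | None = None) -> float:
    """Score of the emitted columns under the match/mismatch/affine-gap scheme."""
    s = scoring or AlignScoring()
    score = 0.0
    in_gap = False
    for r, q in zip(aln.ref_aln, aln.qry_aln):
        if r == "-" or q == "-":
            if not in_gap:
                score += s.gap_open
                in_gap = True
            score += s.gap_extend
        else:
            in_gap = False
            score += s.match if r == q else s.mismatch
    return score


# ---------------------------------------------------------------------------
# windowed identity


def windowed_identity(aln: PairwiseAlignment, params: LocusParams | None = None) -> SimilarityTrack:
    """Percent identity per non-overlapping window of reference bases.

    Windows tile the reference from position 1; the trailing partial window
    is kept and normalized by its actual width. Query-gap and unaligned
    columns count as mismatches; a window with no aligned query base at all
    is classed ``unaligned``. Reference-gap columns consume no reference
    coordinate and are invisible to the track.
    """
    params = params or LocusParams()
    ref = np.frombuffer(aln.ref_aln.encode(), dtype=np.uint8)
    qry = np.frombuffer(aln.qry_aln.encode(), dtype=np.uint8)
    gap = ord("-")
    ref_cols = ref != gap
    n_ref = int(ref_cols.sum())
    if n_ref == 0:
        raise ValueError("alignment contains no reference bases")
    ref_coord = np.cumsum(ref_cols)  # 1-based ref position per column (0 before first)
    match = ref_cols & (qry != gap) & (ref == qry) & aln.aligned
    covered = ref_cols & (qry != gap) & aln.aligned

    w = params.window
    starts = np.arange(1, n_ref + 1, w)
    ends = np.minimum(starts + w - 1, n_ref)
    win_idx = (ref_coord - 1) // w  # valid only where ref_cols
    n_win = len(starts)
    match_per = np.bincount(win_idx[ref_cols & match], minlength=n_win)
    cov_per = np.bincount(win_idx[ref_cols & covered], minlength=n_win)
    width = ends - starts + 1
    identity = 100.0 * match_per / width
    classes = [
        "unaligned" if cov_per[i] == 0
        else ("high" if identity[i] >= params.high_conservation else "low")
        for i in range(n_win)
    ]
    return SimilarityTrack(
        ref_id=aln.ref_id,
        window_starts=starts,
        window_ends=ends,
        identity=identity,
        classes=classes,
        window=w,
    )


def classify_conserved(
    track: SimilarityTrack,
    annotation_overlay: list[tuple[int, int, str]] | None = None,
) -> list[LabelledSegment]:
    """Merge runs of high-conservation windows and label them by overlay class.

    ``annotation_overlay`` is a list of (start, end, class) spans on
    reference coordinates (e.g. toxin / transport / regulation); a segment
    takes the class covering the majority of its span, ``other`` when none.
    """
    overlay = annotation_overlay or []
    segments: list[LabelledSegment] = []
    run_start = None
    for i, cls in enumerate(track.classes + ["low"]):  # sentinel flush
        if cls == "high" and run_start is None:
            run_start = i
        elif cls != "high" and run_start is not None:
            s = int(track.window_starts[run_start])
            e = int(track.window_ends[i - 1])
            cover: dict[str, int] = {}
            for fs, fe, label in overlay:
                ov = min(e, fe) - max(s, fs) + 1
                if ov > 0:
                    cover[label] = cover.get(label, 0) + ov
            label = "other"
            if cover:
                best_label, best_cov = max(sorted(cover.items()), key=lambda kv: kv[1])
                if best_cov > (e - s + 1) / 2:
                    label = best_label
            segments.append(
                LabelledSegment(
                    start=s,
                    end=e,
                    label=label,
                    mean_identity=float(np.mean(track.identity[run_start:i])),
                )
            )
            run_start = None
    return segments


def write_segments_bed(
    segments: list[LabelledSegment], ref_id: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{ref_id}\t{seg.start - 1}\t{seg.end}\t{seg.label}\n")


def plot_track(
    track: SimilarityTrack,
    params: LocusParams | None = None,
    path: str | Path | None = None,
    overlay: list[tuple[int, int, str]] | None = None,
):
    """Peaks-and-valleys conservation plot (floor at plot_floor, shading at
    the high-conservation threshold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = params or LocusParams()
    fig, ax = plt.subplots(figsize=(10, 2.2))
    x = (track.window_starts + track.window_ends) / 2
    y = np.maximum(track.identity, params.plot_floor)
    ax.fill_between(x, params.plot_floor, y, step="mid", color="0.7")
    high = track.identity >= params.high_conservation
    ax.fill_between(x, params.plot_floor, np.where(high, y, params.plot_floor),
                    step="mid", color="firebrick")
    ax.axhline(params.high_conservation, lw=0.5, ls="--", color="k")
    ax.set_ylim(params.plot_floor, 100)
    ax.set_xlabel(f"{track.ref_id} position (bp)")
    ax.set_ylabel("% identity")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
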