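"""Windowed GC and residual cumulative G+C profiling with island calling.

A horizontally acquired segment whose base composition differs from the
host background shows up in the *residual cumulative GC curve* — the
running sum of the per-base GC indicator minus a baseline fraction — as a
stretch of steep non-zero slope ("cline"). With the genome mean as
baseline the curve starts and ends at exactly zero, and its local slope
over any interval equals that interval's GC minus the baseline. Island
calling is therefore a piecewise-linear segmentation of this curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .seq_core import Genome, gc_fraction


@dataclass
class GCProfileParams:
    """Windowing parameters (defaults: 1 kb window advanced in 20 bp steps)."""

    window: int = 1000
    step: int = 20
    baseline: float | Literal["genome_mean"] = "genome_mean"

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError(f"require 0 < step <= window, got {self.step}, {self.window}")


@dataclass
class GCProfile:
    """Windowed GC track and residual cumulative GC sampled on a step grid."""

    genome_id: str
    sample_positions: np.ndarray  # window centers, 1-based
    window_gc: np.ndarray  # fraction per window
    residual_cumulative: np.ndarray  # residual value at each sample position
    baseline_gc: float
    step: int
    window: int
    genome_length: int
    #: residual at the final base (0 up to float error for genome-mean baseline)
    residual_end: float = 0.0

    def __post_init__(self) -> None:
        if not (
            len(self.sample_positions) == len(self.window_gc) == len(self.residual_cumulative)
        ):
            raise ValueError("profile tracks must have equal length")

    def write_bedgraph(self, path: str | Path, track: str = "window_gc") -> None:
        """Write a track as bedGraph (0-based half-open intervals of width step)."""
        values = getattr(self, track)
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{track}"\n')
            for pos, val in zip(self.sample_positions, values):
                start0 = int(pos) - 1
                fh.write(f"{self.genome_id}\t{start0}\t{start0 + self.step}\t{val:.6g}\n")


@dataclass
class IslandCall:
    """A contiguous segment called compositionally foreign."""

    start: int
    end: int
    segment_gc: float
    delta_gc: float
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _indicator_arrays(genome: Genome) -> tuple[np.ndarray, np.ndarray]:
    """Per-base (is_gc, is_unambiguous) uint8 arrays."""
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    return is_gc.astype(np.int64), is_acgt.astype(np.int64)


def _resolve_baseline(genome: Genome, params: GCProfileParams) -> float:
    if params.baseline == "genome_mean":
        return gc_fraction(genome.sequence)
    return float(params.baseline)


def _sample_grid(n: int, params: GCProfileParams) -> np.ndarray:
    """Window start offsets (0-based) for fully contained windows."""
    if n < params.window:
        raise ValueError(f"genome length {n} shorter than window {params.window}")
    return np.arange(0, n - params.window + 1, params.step)


def windowed_gc(genome: Genome, params: GCProfileParams | None = None) -> GCProfile:
    """GC fraction in a sliding window; partial terminal windows are dropped.

    Windows with no unambiguous base get NaN.
    """
    params = params or GCProfileParams()
    n = len(genome)
    offsets = _sample_grid(n, params)
    is_gc, is_acgt = _indicator_arrays(genome)
    cgc = np.concatenate([[0], np.cumsum(is_gc)])
    cok = np.concatenate([[0], np.cumsum(is_acgt)])
    gc_in_win = cgc[offsets + params.window] - cgc[offsets]
    ok_in_win = cok[offsets + params.window] - cok[offsets]
    with np.errstate(divide="ignore", invalid="ignore"):
        wgc = np.where(ok_in_win > 0, gc_in_win / np.maximum(ok_in_win, 1), np.nan)
    baseline = _resolve_baseline(genome, params)
    centers = offsets + params.window // 2 + 1  # 1-based
    residual = _residual_at(genome, centers, baseline)
    return GCProfile(
        genome_id=genome.id,
        sample_positions=centers,
        window_gc=wgc,
        residual_cumulative=residual,
        baseline_gc=baseline,
        step=params.step,
        window=params.window,
        genome_length=n,
        residual_end=float(_residual_at(genome, np.array([n]), baseline)[0]),
    )


def _residual_at(genome: Genome, positions: np.ndarray, baseline: float) -> np.ndarray:
    """Residual cumulative GC at 1-based positions.

    Residual at p = sum over bases 1..p of (gc_indicator - baseline), with
    ambiguous bases contributing zero (neutral), so masked assemblies do
    not create artificial clines.
    """
    is_gc, is_acgt = _indicator_arrays(genome)
    per_base = is_gc - baseline * is_acgt
    cum = np.cumsum(per_base)
    return cum[np.asarray(positions, dtype=np.int64) - 1]


def residual_cumulative_gc(genome: Genome, params: GCProfileParams | None = None) -> GCProfile:
    """Full profile: windowed GC plus residual cumulative GC on one grid."""
    return windowed_gc(genome, params)


def residual_curve(genome: Genome, baseline: float | None = None) -> np.ndarray:
    """Exact per-base residual cumulative GC curve (length N array)."""
    if baseline is None:
        baseline = gc_fraction(genome.sequence)
    return _residual_at(genome, np.arange(1, len(genome) + 1), baseline)


def _chord_split(pos: np.ndarray, res: np.ndarray, lo: int, hi: int, min_span: int) -> int | None:
    """Index of the interior point farthest (vertically) from the lo-hi chord.

    Only points leaving >= min_span bp on both sides qualify; None if no
    such point exists.
    """
    span = pos[hi] - pos[lo]
    if span <= 2 * min_span:
        return None
    mask = (pos[lo + 1 : hi] - pos[lo] >= min_span) & (pos[hi] - pos[lo + 1 : hi] >= min_span)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return None
    i = idx + lo + 1
    chord = res[lo] + (res[hi] - res[lo]) * (pos[i] - pos[lo]) / span
    dev = np.abs(res[i] - chord)
    return int(i[np.argmax(dev)])


def _slope(pos: np.ndarray, res: np.ndarray, a: int, b: int) -> float:
    return float((res[b] - res[a]) / (pos[b] - pos[a]))


def segment_islands(
    profile: GCProfile,
    min_length: int = 5000,
    min_delta: float = 0.03,
    max_segments: int = 12,
) -> list[IslandCall]:
    """Call GC islands by binary change-point segmentation of the residual curve.

    The residual curve is piecewise linear in expectation, with segment
    slope equal to ``segment_gc - baseline``. Recursive chord-deviation
    splitting (deterministic): at each step the interior sample farthest
    from the straight line joining the segment endpoints is a candidate
    boundary, accepted when the slopes on either side differ by at least
    ``min_delta`` (GC-fraction units) and both sides span ``min_length``.
    Adjacent segments closer than ``min_delta`` in slope are re-merged.
    Islands are segments whose |slope| (= |delta_gc|) exceeds ``min_delta``
    and whose span exceeds ``min_length``; boundaries lie on the sample grid.
    """
    if min_length < profile.window:
        import warnings

        warnings.warn(
            f"min_length {min_length} < window {profile.window}: boundary "
            "resolution is coarser than requested",
            stacklevel=2,
        )
    pos = profile.sample_positions.astype(float)
    res = profile.residual_cumulative.astype(float)
    n = len(pos)
    if n < 3:
        return []

    boundaries = [0, n - 1]

    def recurse(lo: int, hi: int, depth: int) -> None:
        if len(boundaries) - 1 >= max_segments or depth > 30:
            return
        cut = _chord_split(pos, res, lo, hi, min_length)
        if cut is None:
            return
        left, right = _slope(pos, res, lo, cut), _slope(pos, res, cut, hi)
        if abs(left - right) < min_delta:
            return
        boundaries.append(cut)
        boundaries.sort()
        recurse(lo, cut, depth + 1)
        recurse(cut, hi, depth + 1)

    recurse(0, n - 1, 0)

    def refine(lo: int, b: int, hi: int) -> int:
        """Exact least-squares single-change-point re-estimate of b in (lo, hi).

        Fits a constant mean to the residual increments on each side; the
        SSE-optimal cut maximizes sum_1^2/n_1 + sum_2^2/n_2 (invariant to
        the baseline tilt).
        """
        cand = np.arange(lo + 1, hi)
        if cand.size == 0:
            return b
        n1 = pos[cand] - pos[lo]
        n2 = pos[hi] - pos[cand]
        s1 = res[cand] - res[lo]
        s2 = res[hi] - res[cand]
        crit = s1 * s1 / n1 + s2 * s2 / n2
        return int(cand[np.argmax(crit)])

    # alternate boundary refinement with merging of near-equal slopes
    for _ in range(6):
        changed = False
        for j in range(1, len(boundaries) - 1):
            new_b = refine(boundaries[j - 1], boundaries[j], boundaries[j + 1])
            if new_b != boundaries[j]:
                boundaries[j] = new_b
                changed = True
        merged = True
        while merged and len(boundaries) > 2:
            merged = False
            for j in range(1, len(boundaries) - 1):
                a, b, c = boundaries[j - 1], boundaries[j], boundaries[j + 1]
                if abs(_slope(pos, res, a, b) - _slope(pos, res, b, c)) < min_delta:
                    boundaries.pop(j)
                    merged = changed = True
                    break
            if merged:
                continue
            # absorb sub-min_length slivers into the slope-closest neighbor
            for j in range(len(boundaries) - 1):
                a, b = boundaries[j], boundaries[j + 1]
                if pos[b] - pos[a] >= min_length:
                    continue
                s = _slope(pos, res, a, b)
                left = (
                    abs(s - _slope(pos, res, boundaries[j - 1], a)) if j > 0 else np.inf
                )
                right = (
                    abs(s - _slope(pos, res, b, boundaries[j + 2]))
                    if j + 2 < len(boundaries)
                    else np.inf
                )
                if left is np.inf and right is np.inf:
                    continue
                boundaries.pop(j if left <= right else j + 1)
                merged = changed = True
                break
        if not changed:
            break

    calls: list[IslandCall] = []
    for j in range(len(boundaries) - 1):
        a, b = boundaries[j], boundaries[j + 1]
        delta = _slope(pos, res, a, b)
        length = pos[b] - pos[a]
        if abs(delta) < min_delta or length < min_length:
            continue
        contrasts = []
        if j > 0:
            contrasts.append(abs(delta - _slope(pos, res, boundaries[j - 1], a)))
        if j + 2 < len(boundaries):
            contrasts.append(abs(delta - _slope(pos, res, b, boundaries[j + 2])))
        score = min(contrasts) if contrasts else abs(delta)
        calls.append(
            IslandCall(
                start=int(pos[a]),
                end=int(pos[b]),
                segment_gc=profile.baseline_gc + delta,
                delta_gc=delta,
                score=score,
            )
        )
    calls.sort(key=lambda c: c.start)
    return calls


def write_islands_bed(calls: list[IslandCall], genome_id: str, path: str | Path) -> None:
    """Write island calls as BED6 (score = |delta_gc| x 1000, clipped to 1000)."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, 1):
            score = min(int(round(abs(c.delta_gc) * 1000)), 1000)
            fh.write(
                f"{genome_id}\t{c.start - 1}\t{c.end}\tisland_{i}\t{score}\t.\n"
            )
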