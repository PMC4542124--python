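# Methods

`mosaictox` re-implements, as a tested library, the comparative-genomics
workflow used to argue that a bacterial insecticidal-toxin cluster (the
FitD/Mcf family shared between plant-associated *Pseudomonas* and the
insect pathogens *Photorhabdus*/*Xenorhabdus*) was acquired horizontally
and evolved as a mosaic. The evidence chain has five quantitative legs,
each its own module: compositional anomaly at the genome scale
(`gc_profile`), compositional anomaly at the gene scale
(`gene_gc_stats`), piecewise conservation structure of the toxin locus
(`locus_compare`), model-based recombination detection
(`breakpoint_scan`), and phylogenetic incongruence (`phylo`). A
generator module (`synthetic_data`) produces inputs with known ground
truth so every stage is verifiable offline.

## Residual cumulative GC profiling and island calling

For a genome of length N with per-base GC indicator x_i and baseline
fraction ḡ (genome mean by default), the residual cumulative GC curve is

    R(p) = Σ_{i=1..p} (x_i − ḡ),   p = 1..N.

With the genome-mean baseline R(0) = R(N) = 0 exactly, and the slope of
R over any interval equals that interval's GC content minus ḡ. A
compositionally foreign segment therefore appears as a straight cline of
slope ΔGC. The windowed GC track (default 1 kb window, 20 bp step, both
taken from the published protocol) and R sampled on the same grid make
up a `GCProfile`. Ambiguous bases (N and other IUPAC codes) contribute
zero residual and are excluded from GC numerators and denominators, so
masked draft assemblies do not produce artificial clines.

Island calling is a deterministic piecewise-linear segmentation of R:

1. **Recursive chord splitting.** Within a segment, the sample farthest
   (vertically) from the chord joining the segment endpoints is a
   candidate boundary; it is accepted when the slopes on either side
   differ by at least `min_delta` (GC-fraction units, default 0.03) and
   both sides span at least `min_length` (default 5 kb).
2. **Least-squares refinement.** Each interior boundary is re-estimated
   between its neighbors as the exact single-change-point least-squares
   optimum of the residual increments (the CUSUM argmax with both
   segment means free). This removes the bias the chord heuristic has
   when the flanking slopes are asymmetric.
3. **Merging.** Adjacent segments with slope difference < `min_delta`
   are merged, and segments shorter than `min_length` are absorbed into
   the slope-closest neighbor. Refinement and merging alternate to a
   fixed point.

Reported islands are segments with |slope| ≥ `min_delta` and span ≥
`min_length`; `delta_gc` is the segment slope and `segment_gc` =
baseline + slope. Boundaries lie on the 20 bp sample grid. The defaults
were chosen so that a 20 kb island at ΔGC = −0.15 in a 200 kb background
(the magnitude of the published toxin-island signal) is recovered with
boundary error well under 500 bp, while a homogeneous genome yields no
calls: under the i.i.d. base model the slope estimate over 5 kb has
standard deviation ≈ 0.007, putting `min_delta` = 0.03 at >4σ.

## Gene-level GC statistics

`gene_gc_table` computes per-gene GC (strand-invariant, ambiguity codes
excluded) and the genome-wide GC; percentages are rounded half-up to one
decimal for display only. `gc_percentile(records, focal)` returns the
fraction of *other* genes whose full-precision GC is ≥ the focal gene's
— the "how exceptional is this gene" statistic; counting the focal gene
itself is available via a switch.

## Locus comparison (windowed identity)

Toxin loci are extracted with 25 kb flanks on each side of the gene and
oriented so the toxin reads left to right. Pairs of loci are aligned
with a seed-chain-extend anchored global aligner:

- anchors are exact-match k-mers (k = 12) unique in both sequences,
  merged along diagonals;
- the chain maximizing total anchored length over co-linear,
  non-overlapping anchors is found by a Fenwick-tree sweep
  (O(n log n));
- inter-anchor gaps up to `max_gap` (2 kb) are closed by affine-gap
  global alignment (match +1, mismatch −1, gap open −4, gap extend −1);
  larger gaps are emitted unaligned and flagged per column.

This is a functional substitute for the LAGAN-class aligner used in the
original VISTA protocol; no column-level equivalence is claimed, only
window-level identity behavior. Identity is reported per non-overlapping
100 bp window of *reference* coordinates: matches / window width × 100,
with query-gap and unaligned columns counted as mismatches (this keeps
the 50–100 % plot floor meaningful) and reference-gap columns invisible
by construction. Windows with no aligned query base are classed
`unaligned`; runs of windows ≥ 70 % identity merge into conserved
segments labelled by an optional annotation overlay (toxin / transport /
regulation), majority rule, `other` otherwise. The trailing partial
window is kept and normalized by its actual width.

## Substitution models and likelihood

JC69, K80 and HKY85 are implemented as one family: HKY85's rate matrix
with transition/transversion ratio κ and stationary frequencies π,
normalized to one expected substitution per site, with JC69 (κ = 1,
equal π) and K80 (equal π) as special cases. P(t) = exp(Qt) comes from
the symmetric eigendecomposition available for reversible Q. HKY85 base
frequencies are empirical (counted from the alignment) and therefore not
counted as free parameters.

`loglik` is Felsenstein pruning with site-pattern compression; gaps and
ambiguity codes are missing data (partial likelihood 1 in every state).
Branch lengths are optimized coordinate-wise by Brent's method in
log-branch-length space (bracket ±0.7 around the current value, bounded
fallback), cycling until the log-likelihood gain per cycle falls below
`tol`; each accepted move is checked to be non-decreasing, so the
optimizer is monotone by construction. κ is estimated by bounded Brent
on [0.05, 100], keeping the incumbent when the search does not improve.

Distances: JC69 and K80 use their closed forms (capped at 5.0
substitutions/site with a warning when the transform is undefined);
HKY85 uses per-pair ML optimization of t with fixed κ and empirical π;
protein rows use the Poisson correction −ln(1 − p). Trees come from
Saitou–Nei neighbor joining with deterministic lexicographic
tie-breaking; negative branch lengths are clamped to zero with the
deficit moved to the sibling so pairwise path lengths are preserved.
Full ML topology search (PhyML-style) is deliberately out of scope: NJ
on model distances plus ML branch lengths is what the breakpoint scan
needs, and topology-level claims are made qualitatively. Bootstrap
support is the fraction of B column-resamples (seeded, B = 100 by
default per the published protocol) whose NJ tree contains the same
bipartition; alignments with no variable column report NA.

The conserved-block filter follows the Gblocks defaults in simplified
form: a column is conserved when its majority residue reaches
⌊n/2⌋+1 sequences and highly conserved at ≥ 0.85 n; runs of more than 8
nonconserved columns are removed, blocks are trimmed to highly conserved
flanks, blocks shorter than 10 columns are dropped, and (by default) any
column containing a gap is removed. Column-for-column equivalence with
Gblocks is not promised; the kept-column map is returned for
traceability.

## Single-breakpoint recombination scan

For every candidate column p on a stride grid (default stride 10, both
segments ≥ `min_segment` = 200 columns), two phylogenies are fitted
independently to columns 1..p and p+1..L and compared with one
phylogeny fitted to the whole alignment by

    AICc = 2k − 2 lnL + 2k(k+1)/(n − k − 1),

with n = total alignment columns (configurable to variable columns) and
k = branch lengths (2·taxa − 3) plus one per estimated κ. The verdict is
"breakpoint" when the best candidate's AICc improvement reaches
`delta_aicc_threshold` (default 10); ties break toward the smaller
position. Each segment fit evaluates both the segment's own NJ topology
and the whole-data topology warm-started from the single fit's branch
lengths, keeping the better; because the warm start can only improve
monotonically, lnL_left + lnL_right ≥ lnL_single holds at every
candidate by construction. The original analysis used a
genetic-algorithm server implementation; at these data sizes an
exhaustive deterministic grid scan is feasible and reproducible, so that
is what is implemented. Segment fits use a relaxed optimizer tolerance
(0.01 lnL units, ample against a decision threshold of 10 AICc units).

## Synthetic data

All generators are pure functions of (parameters, seed); seeds are
mandatory, and every simulation returns a serializable truth record
sufficient to score recovery without re-simulation.

- `simulate_genome`: i.i.d. bases with P(G) = P(C) = gc/2 per segment;
  islands are non-overlapping spans with their own GC. No dinucleotide
  or codon structure — sufficient for testing a method that only reads
  composition, but real genomes have autocorrelated composition, so
  false-positive rates measured here are optimistic for real data.
- `simulate_annotation`: genes tiled left-to-right with random 0–200 bp
  gaps; per-gene target GC drawn from N(background, 0.02) — the
  gene-to-gene spread that makes the GC-percentile statistic
  non-degenerate — with one focal gene placed exactly at background +
  offset.
- `evolve_alignment`: root sequence from the stationary distribution,
  exact P(t) per edge, site-independent, no indels. Alignment columns
  are therefore homologous by construction; mosaic tests in
  `locus_compare` splice segments of differing divergence instead of
  simulating indels.
- `simulate_recombinant`: two `evolve_alignment` calls (independent
  sub-seeds) concatenated at a known breakpoint column.
- `synthetic_toxin_template`: a 9006 bp random sequence at the toxin
  gene's GC carrying the published screening-primer footprints at their
  published gene-local positions (fit1 pair spanning 2..962, fit2 pair
  spanning 4828..5702). Only the primer-site geometry is faithful; the
  rest is random — it is a synthetic stand-in, used to verify amplicon
  arithmetic, not sequence content.

## In-silico PCR

Primer sites are found by direct scanning of both strands with
IUPAC-aware matching (primer base set ∩ template base set non-empty),
at most `max_mismatch` mismatches and an exact 3'-terminal clamp
(default 3 bases). Amplicons pair a plus-strand site of either primer
with a downstream minus-strand site of the other; the reported interval
includes both primer footprints, which reproduces the published
875 bp product from its printed 4828–5702 positions. No thermodynamics
(Tm, dimers) — the original specificity check was BLASTN-based, i.e.
pure sequence matching.

## Test conditions and what they show

The property-based acceptance checks run at these problem sizes, chosen
to match the magnitudes reported for the real loci while keeping the
suite fast: island recovery on 200 kb genomes with one 20 kb island at
ΔGC 0.15 (20 seeds; ≥ 19/20 within ±500 bp); breakpoint scans on
4-taxon alignments — 2000 columns non-recombinant for the
false-positive rate (≤ 2/20) and 3000 columns with a switch at column
1200 for recovery (≥ 18/20 within ±60 columns), scanned under JC69 with
inner branches 0.1; likelihood checked against brute-force
internal-state enumeration on trees with ≤ 3 internal nodes to 1e-10.
Passing these shows the machinery is correct under the stated generative
models; it does not certify error rates on real genomes, where
composition is autocorrelated, alignments contain indels and
rate variation, and annotations are imperfect.

## Known limitations

- Gene/genome GC values for the real public accessions (and the
  host-genome GC-percentile of the real toxin gene) require those
  genomes on disk; the package computes them from any FASTA + feature
  table, but ships no genome sequences. The corresponding acceptance
  tests fail with instructions when the sequences are absent.
- NJ + ML branch lengths is not a full ML topology search; bootstrap
  values are not comparable to published PhyML trees beyond grouping
  structure.
- The anchored aligner targets locus-scale (≤ ~100 kb) pairs; it is not
  a whole-genome aligner and has no translated mode.
- Circular genomes are treated as linear from position 1; regions may
  not wrap the origin.
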