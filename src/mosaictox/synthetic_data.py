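"""Synthetic-data generators with machine-readable ground truth.

Every analysis stage in this package can be exercised offline against
data whose true structure is known: i.i.d. genomes with embedded
GC-shifted islands, annotated gene sets with a designated
composition-outlier gene, alignments evolved site-independently on known
trees under the HKY85 family, and recombinant alignments whose genealogy
switches topology at a known column. Generators are pure functions of
(parameters, seed); each returns its result together with a serializable
:class:`SimTruth` sufficient to score recovery without re-simulation.

Deliberate simplifications: bases are i.i.d. within a segment (no
dinucleotide or codon structure) and sequence evolution has no indels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import dendropy
import numpy as np

from .models import STATES, SubstitutionModel, TransitionProbabilities
from .phylo import MultipleAlignment, read_newick
from .seq_core import GeneFeature, Genome


@dataclass
class IslandSpec:
    start: int  # 1-based
    length: int
    gc: float

    def __post_init__(self) -> None:
        if not (0 < self.gc < 1):
            raise ValueError("island gc must be in (0, 1)")
        if self.start < 1 or self.length < 1:
            raise ValueError("invalid island span")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SimTruth:
    generator: str
    seed: int
    parameters: dict[str, Any]
    truth: dict[str, Any]

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "generator": self.generator,
                    "seed": self.seed,
                    "parameters": self.parameters,
                    "truth": self.truth,
                },
                fh,
                indent=1,
            )

    @classmethod
    def read_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["generator"], d["seed"], d["parameters"], d["truth"])


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def simulate_genome(
    length: int,
    background_gc: float,
    islands: list[IslandSpec] | None = None,
    seed: int | None = None,
    genome_id: str = "sim_genome",
) -> tuple[Genome, SimTruth]:
    """i.i.d. genome with GC-shifted islands at known coordinates.

    Within each segment P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    Islands must be non-overlapping and inside the genome.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if not (0 < background_gc < 1):
        raise ValueError("background_gc must be in (0, 1)")
    islands = sorted(islands or [], key=lambda i: i.start)
    prev_end = 0
    for isl in islands:
        if isl.start <= prev_end:
            raise ValueError("islands overlap")
        if isl.end > length:
            raise ValueError("island extends past genome end")
        prev_end = isl.end
    rng = np.random.default_rng(seed)
    arr = _draw_bases(rng, length, background_gc)
    for isl in islands:
        arr[isl.start - 1 : isl.end] = _draw_bases(rng, isl.length, isl.gc)
    genome = Genome(id=genome_id, sequence=arr.tobytes().decode("ascii"))
    truth = SimTruth(
        generator="simulate_genome",
        seed=seed,
        parameters={"length": length, "background_gc": background_gc},
        truth={
            "islands": [
                {"start": i.start, "end": i.end, "gc": i.gc} for i in islands
            ]
        },
    )
    return genome, truth


def simulate_annotation(
    genome: Genome,
    n_genes: int,
    gene_length_range: tuple[int, int] = (600, 1500),
    focal_gene_gc_offset: float = 0.0,
    gene_gc_sd: float = 0.02,
    background_gc: float | None = None,
    seed: int | None = None,
) -> tuple[Genome, list[GeneFeature], SimTruth]:
    """Tile non-overlapping genes onto a genome; one focal composition outlier.

    Genes are placed left to right with random intergenic gaps. Each gene
    span is re-drawn at a target GC sampled from N(background_gc,
    gene_gc_sd) — the gene-to-gene compositional spread real genomes show
    — except the focal gene (the middle one), drawn at exactly
    ``background_gc + focal_gene_gc_offset`` to emulate a horizontally
    acquired gene sitting in a host genome. Returns the modified genome,
    the features, and truth recording the focal id and realized per-gene
    GC.
    """
    if seed is None:
        raise ValueError("a seed is required")
    from .seq_core import gc_fraction

    rng = np.random.default_rng(seed)
    if background_gc is None:
        background_gc = gc_fraction(genome.sequence)
    lo, hi = gene_length_range
    n = len(genome)
    feats: list[GeneFeature] = []
    pos = 1
    for i in range(n_genes):
        glen = int(rng.integers(lo, hi + 1))
        gap = int(rng.integers(0, 200))
        start = pos + gap
        end = start + glen - 1
        if end > n:
            raise ValueError(
                f"cannot pack {n_genes} genes of {lo}-{hi} bp into {n} bp"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(GeneFeature(f"gene_{i + 1:04d}", start, end, strand))
        pos = end + 1
    focal = feats[n_genes // 2]
    focal_gc_target = background_gc + focal_gene_gc_offset
    if not (0 < focal_gc_target < 1):
        raise ValueError("focal GC target outside (0, 1)")
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8).copy()
    for f in feats:
        if f is focal:
            target = focal_gc_target
        else:
            target = float(np.clip(rng.normal(background_gc, gene_gc_sd), 0.05, 0.95))
        arr[f.start - 1 : f.end] = _draw_bases(rng, f.length, target)
    genome = Genome(id=genome.id, sequence=arr.tobytes().decode("ascii"))
    per_gene_gc = {
        f.feature_id: gc_fraction(genome.sequence[f.start - 1 : f.end]) for f in feats
    }
    truth = SimTruth(
        generator="simulate_annotation",
        seed=seed,
        parameters={
            "n_genes": n_genes,
            "gene_length_range": list(gene_length_range),
            "focal_gene_gc_offset": focal_gene_gc_offset,
            "background_gc": background_gc,
        },
        truth={"focal_id": focal.feature_id, "per_gene_gc": per_gene_gc},
    )
    return genome, feats, truth


def write_features_tsv(features: list[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.feature_id}\t{f.start}\t{f.end}\t{f.strand}\n")


def _as_tree(tree: dendropy.Tree | str) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return read_newick(tree)


def evolve_alignment(
    tree: dendropy.Tree | str,
    model: SubstitutionModel,
    length: int,
    seed: int | None = None,
) -> tuple[MultipleAlignment, SimTruth]:
    """Evolve a gap-free alignment site-independently along a tree.

    The root sequence is drawn from the model's stationary frequencies and
    each edge applies its exact transition matrix P(branch length); no
    indels. Taxa appear in sorted leaf-label order.
    """
    if seed is None:
        raise ValueError("a seed is required")
    tree = _as_tree(tree)
    model = model.resolved(np.full(4, 0.25)) if model.base_freqs is None else model
    probs = TransitionProbabilities(model)
    rng = np.random.default_rng(seed)

    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.choice(4, size=length, p=model.base_freqs)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is root:
            continue
        parent_seq = seqs[id(edge.tail_node)]
        t = edge.length or 0.0
        if t <= 0:
            child = parent_seq.copy()
        else:
            P = probs(t)
            child = np.empty_like(parent_seq)
            for state in range(4):
                idx = np.nonzero(parent_seq == state)[0]
                if idx.size:
                    child[idx] = rng.choice(4, size=idx.size, p=P[state])
        seqs[id(edge.head_node)] = child

    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    rows = ["".join(STATES[s] for s in seqs[id(nd)]) for nd in leaves]
    aln = MultipleAlignment([nd.taxon.label for nd in leaves], rows, "nucleotide")
    truth = SimTruth(
        generator="evolve_alignment",
        seed=seed,
        parameters={
            "model": model.name,
            "kappa": model.kappa,
            "length": length,
        },
        truth={"newick": tree.as_string(schema="newick").strip()},
    )
    return aln, truth


def simulate_recombinant(
    tree_left: dendropy.Tree | str,
    tree_right: dendropy.Tree | str,
    breakpoint_column: int,
    model: SubstitutionModel,
    length: int,
    seed: int | None = None,
) -> tuple[MultipleAlignment, SimTruth]:
    """Alignment whose genealogy switches topology after a known column.

    Columns 1..breakpoint evolve on ``tree_left``, the rest on
    ``tree_right``; both trees must share the same leaf set.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if not (0 < breakpoint_column < length):
        raise ValueError("breakpoint must fall strictly inside the alignment")
    tl, tr = _as_tree(tree_left), _as_tree(tree_right)
    leaves_l = {nd.taxon.label for nd in tl.leaf_node_iter()}
    leaves_r = {nd.taxon.label for nd in tr.leaf_node_iter()}
    if leaves_l != leaves_r:
        raise ValueError(f"leaf sets differ: {sorted(leaves_l ^ leaves_r)}")
    ss = np.random.SeedSequence(seed)
    s_left, s_right = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    left, _ = evolve_alignment(tl, model, breakpoint_column, seed=s_left)
    right, _ = evolve_alignment(tr, model, length - breakpoint_column, seed=s_right)
    rows = [left.row(t) + right.row(t) for t in left.taxa]
    aln = MultipleAlignment(list(left.taxa), rows, "nucleotide")
    truth = SimTruth(
        generator="simulate_recombinant",
        seed=seed,
        parameters={"model": model.name, "kappa": model.kappa, "length": length},
        truth={
            "breakpoint_column": breakpoint_column,
            "newick_left": tl.as_string(schema="newick").strip(),
            "newick_right": tr.as_string(schema="newick").strip(),
        },
    )
    return aln, truth


def synthetic_toxin_template(seed: int | None = None, gc: float = 0.651) -> Genome:
    """Synthetic stand-in for a fitD-class toxin gene as a PCR template.

    A 9006 bp i.i.d. sequence at the gene's typical GC content carrying
    the published screening-primer footprints at their published
    gene-local positions: the fit1f/fit1r pair spanning 2..962 and the
    fit2f/fit2r pair spanning 4828..5702. Everything outside the primer
    footprints is random, so this is NOT the real gene — only primer-site
    geometry is faithful.
    """
    if seed is None:
        raise ValueError("a seed is required")
    from .insilico_pcr import FIT1F, FIT1R, FIT2F, FIT2R
    from .seq_core import reverse_complement

    rng = np.random.default_rng(seed)
    arr = _draw_bases(rng, 9006, gc)

    def plant(seq: str, start: int) -> None:  # 1-based start
        arr[start - 1 : start - 1 + len(seq)] = np.frombuffer(seq.encode(), np.uint8)

    plant(FIT1F.sequence, 2)
    plant(reverse_complement(FIT1R.sequence), 962 - len(FIT1R.sequence) + 1)
    plant(FIT2F.sequence, 4828)
    plant(reverse_complement(FIT2R.sequence), 5702 - len(FIT2R.sequence) + 1)
    return Genome(id="synthetic_fitD_template", sequence=arr.tobytes().decode("ascii"))


def mosaic_locus_pair(
    segment_specs: list[tuple[int, float]],
    seed: int | None = None,
) -> tuple[str, str, SimTruth]:
    """Homologous locus pair with piecewise divergence (mosaic structure).

    ``segment_specs`` is a list of (length, divergence) pairs; each
    segment of the query is either a mutated copy of the reference
    (per-site substitution probability = divergence) or, at divergence
    >= 1.0, an unrelated random sequence. No indels, so coordinates match
    between the two sequences.
    """
    if seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref_parts, qry_parts, bounds = [], [], []
    pos = 1
    for length, div in segment_specs:
        ref = rng.choice(bases, size=length)
        if div >= 1.0:
            qry = rng.choice(bases, size=length)
        else:
            qry = ref.copy()
            mut = rng.random(length) < div
            # substitute to a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=int(mut.sum()))
            state = np.searchsorted(bases, qry[mut])
            qry[mut] = bases[(state + shift) % 4]
        ref_parts.append(ref)
        qry_parts.append(qry)
        bounds.append({"start": pos, "end": pos + length - 1, "divergence": div})
        pos += length
    ref_seq = np.concatenate(ref_parts).tobytes().decode()
    qry_seq = np.concatenate(qry_parts).tobytes().decode()
    truth = SimTruth(
        generator="mosaic_locus_pair",
        seed=seed,
        parameters={"segments": [list(s) for s in segment_specs]},
        truth={"segments": bounds},
    )
    return ref_seq, qry_seq, truth
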