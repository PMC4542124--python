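"""Distance/NJ phylogenetics with a Felsenstein-pruning likelihood engine.

Covers the multilocus workflow used to argue phylogenetic incongruence of
a horizontally mobile locus: concatenation of housekeeping-gene
alignments, conserved-block filtering of the kind popularized by Gblocks,
model-based pairwise distances, neighbor joining with nonparametric
bootstrap, maximum-likelihood branch lengths on a fixed topology, and
Robinson–Foulds comparison between gene trees.

Full ML topology search is deliberately not attempted: trees come from NJ
on model distances and are then refined by ML branch-length optimization,
which is what the downstream breakpoint scan needs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO
from scipy.optimize import minimize_scalar

from .models import (
    STATE_INDEX,
    STATES,
    SubstitutionModel,
    TransitionProbabilities,
    empirical_base_freqs,
)

logger = logging.getLogger(__name__)

#: distance assigned when the model transform is undefined (saturation)
DISTANCE_CAP = 5.0


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class MultipleAlignment:
    taxa: list[str]
    rows: list[str]
    type: str = "nucleotide"  # or "protein"
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def subset_columns(self, start: int, end: int) -> "MultipleAlignment":
        """Columns start..end, 1-based inclusive."""
        return MultipleAlignment(
            list(self.taxa), [r[start - 1 : end] for r in self.rows], self.type
        )

    @classmethod
    def read_fasta(cls, path: str | Path, type: str = "nucleotide") -> "MultipleAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"{path}: no records")
        return cls([r.id for r in recs], [str(r.seq) for r in recs], type)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")

    def write_partitions(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("partition\tstart\tend\n")
            for name, s, e in self.partitions:
                fh.write(f"{name}\t{s}\t{e}\n")


def concat_alignments(alignments: list[MultipleAlignment]) -> MultipleAlignment:
    """Concatenate per-gene alignments over a shared taxon set.

    Taxa are matched by id (input row order is irrelevant; output is
    sorted by id) and partition boundaries are recorded.
    """
    if not alignments:
        raise ValueError("no alignments given")
    taxon_set = set(alignments[0].taxa)
    for i, a in enumerate(alignments[1:], 2):
        if set(a.taxa) != taxon_set:
            missing = taxon_set ^ set(a.taxa)
            raise ValueError(f"alignment {i} taxon mismatch: {sorted(missing)}")
    taxa = sorted(taxon_set)
    rows = ["".join(a.row(t) for a in alignments) for t in taxa]
    partitions = []
    pos = 1
    for i, a in enumerate(alignments, 1):
        partitions.append((f"partition_{i}", pos, pos + a.n_columns - 1))
        pos += a.n_columns
    return MultipleAlignment(taxa, rows, alignments[0].type, partitions)


# ---------------------------------------------------------------------------
# conserved-block filtering


@dataclass
class BlockFilterParams:
    """Thresholds for conserved-block filtering (Gblocks-style defaults).

    A column is *conserved* when its majority residue count reaches
    ``floor(n * min_conserved_fraction) + 1`` sequences, and *highly
    conserved* when it reaches ``ceil(n * min_flank_fraction)``. Runs of
    more than ``max_nonconserved_run`` nonconserved columns are removed,
    blocks are trimmed to highly-conserved flanks, and blocks shorter than
    ``min_block_length`` are dropped.
    """

    min_conserved_fraction: float = 0.5
    min_flank_fraction: float = 0.85
    max_nonconserved_run: int = 8
    min_block_length: int = 10
    allow_gaps: str = "none"  # none | half

    def __post_init__(self) -> None:
        for f in (self.min_conserved_fraction, self.min_flank_fraction):
            if not (0 < f <= 1):
                raise ValueError("fractions must be in (0, 1]")
        if self.allow_gaps not in ("none", "half"):
            raise ValueError("allow_gaps must be 'none' or 'half'")


def block_filter(
    alignment: MultipleAlignment, params: BlockFilterParams | None = None
) -> tuple[MultipleAlignment, list[int]]:
    """Remove poorly aligned segments; returns filtered alignment and the
    1-based indices of kept columns."""
    params = params or BlockFilterParams()
    n = alignment.n_taxa
    L = alignment.n_columns
    conserved_count = math.floor(n * params.min_conserved_fraction) + 1
    high_count = math.ceil(n * params.min_flank_fraction)

    # 0 = rejected, 1 = nonconserved, 2 = conserved, 3 = highly conserved
    status = np.zeros(L, dtype=np.int8)
    cols = np.array([list(r) for r in alignment.rows])
    for j in range(L):
        col = cols[:, j]
        gaps = int(np.sum(col == "-"))
        if (params.allow_gaps == "none" and gaps > 0) or (
            params.allow_gaps == "half" and gaps >= n / 2
        ):
            continue  # rejected
        residues, counts = np.unique(col[col != "-"], return_counts=True)
        m = int(counts.max()) if counts.size else 0
        if m >= high_count:
            status[j] = 3
        elif m >= conserved_count:
            status[j] = 2
        else:
            status[j] = 1

    # remove over-long nonconserved runs (contiguity broken by rejections)
    j = 0
    while j < L:
        if status[j] == 1:
            k = j
            while k < L and status[k] == 1:
                k += 1
            if k - j > params.max_nonconserved_run:
                status[j:k] = 0
            j = k
        else:
            j += 1

    # blocks between rejected columns, trimmed to highly conserved flanks
    kept: list[int] = []
    j = 0
    while j < L:
        if status[j] == 0:
            j += 1
            continue
        k = j
        while k < L and status[k] != 0:
            k += 1
        high = [i for i in range(j, k) if status[i] == 3]
        if high:
            block = list(range(high[0], high[-1] + 1))
            if len(block) >= params.min_block_length:
                kept.extend(block)
        j = k

    if not kept:
        warnings.warn("block filter removed every column", stacklevel=2)
    filtered = MultipleAlignment(
        list(alignment.taxa),
        ["".join(r[i] for i in kept) for r in alignment.rows],
        alignment.type,
    )
    return filtered, [i + 1 for i in kept]


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for t, row in zip(self.taxa, self.matrix):
                fh.write(t[:10].ljust(10) + "  " + "  ".join(f"{d:.6f}" for d in row) + "\n")


def _encode_row(row: str) -> np.ndarray:
    """ACGT -> 0..3, everything else -> -1."""
    arr = np.frombuffer(row.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in STATE_INDEX.items():
        codes[arr == ord(b)] = i
    return codes


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """4x4 substitution count matrix over pairwise complete unambiguous sites."""
    ok = (a >= 0) & (b >= 0)
    return np.bincount(
        (a[ok].astype(np.int64) * 4 + b[ok]), minlength=16
    ).reshape(4, 4).astype(float)


def _jc69(p: float) -> float:
    if p >= 0.75 - 1e-12:
        warnings.warn(f"JC69 undefined at p={p:.3f}; capping distance", stacklevel=3)
        return DISTANCE_CAP
    return -0.75 * math.log(1 - 4 * p / 3)


def _k80(P: float, Q: float) -> float:
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 1e-12 or w2 <= 1e-12:
        warnings.warn("K80 transform undefined; capping distance", stacklevel=3)
        return DISTANCE_CAP
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def _hky_ml_distance(
    counts: np.ndarray,
    model: SubstitutionModel,
    probs: TransitionProbabilities | None = None,
) -> float:
    """Pairwise ML distance under HKY85 with fixed kappa and frequencies."""
    probs = probs or TransitionProbabilities(model)
    pi = model.base_freqs

    def neg_ll(t: float) -> float:
        P = np.maximum(probs(t), 1e-300)
        return -float(np.sum(counts * np.log(pi[:, None] * P)))

    res = minimize_scalar(neg_ll, bounds=(1e-8, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def pairwise_distance(alignment: MultipleAlignment, model: SubstitutionModel) -> DistanceMatrix:
    """Model-corrected pairwise distances.

    Nucleotide rows use the JC69/K80 closed forms or pairwise-ML HKY85;
    protein rows use the Poisson correction -ln(1 - p). Sites with a gap
    or ambiguity in either sequence are skipped pairwise. Undefined
    transforms (saturation) are capped at ``DISTANCE_CAP`` with a warning.
    """
    n = alignment.n_taxa
    D = np.zeros((n, n))
    if alignment.type == "protein":
        for i in range(n):
            for j in range(i + 1, n):
                pairs = [
                    (x, y)
                    for x, y in zip(alignment.rows[i], alignment.rows[j])
                    if x not in "-X?" and y not in "-X?"
                ]
                if not pairs:
                    raise ValueError(f"no complete sites between rows {i} and {j}")
                p = sum(x != y for x, y in pairs) / len(pairs)
                D[i, j] = D[j, i] = (
                    DISTANCE_CAP if p >= 1 - 1e-12 else -math.log(1 - p)
                )
        return DistanceMatrix(list(alignment.taxa), D)

    model = model.resolved(empirical_base_freqs(alignment.rows))
    probs = TransitionProbabilities(model) if model.name == "HKY85" else None
    coded = [_encode_row(r) for r in alignment.rows]
    for i in range(n):
        for j in range(i + 1, n):
            counts = _pair_counts(coded[i], coded[j])
            total = counts.sum()
            if total == 0:
                raise ValueError(f"no complete sites between rows {i} and {j}")
            p = (total - np.trace(counts)) / total
            if model.name == "JC69":
                d = _jc69(p)
            elif model.name == "K80":
                ts = counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1]
                d = _k80(ts / total, (total - np.trace(counts) - ts) / total)
            else:
                d = _hky_ml_distance(counts, model, probs)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(alignment.taxa), D)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(
    dm: DistanceMatrix, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Deterministic: ties in the Q criterion are broken toward the
    lexicographically smallest (representative) taxon pair. Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling branch, preserving the pairwise path length.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    ns = taxon_namespace or dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # representative (smallest) leaf label per cluster
    for label in dm.taxa:
        taxon = ns.get_taxon(label) or ns.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        reps.append(label)
    D = dm.matrix.copy()
    active = list(range(n))

    def join(i: int, j: int, bi: float, bj: float) -> int:
        """Join active clusters i, j under a new node; returns new index."""
        nonlocal D
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        parent = dendropy.Node()
        ci, cj = nodes[i], nodes[j]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = max(bi, 0.0)
        cj.edge.length = max(bj, 0.0)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        return len(nodes) - 1

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        # choose minimal Q with deterministic tie-break
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                key = (round(q, 10), *sorted((reps[active[a]], reps[active[b]])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        bi = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        bj = dij - bi
        new = join(i, j, bi, bj)
        # distances from the new cluster
        newrow = np.zeros(len(nodes))
        for c in range(m):
            kidx = active[c]
            if kidx in (i, j):
                continue
            newrow[kidx] = 0.5 * (D[i, kidx] + D[j, kidx] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, : new] = newrow[:new]
        D[:new, new] = newrow[:new]
        active = [x for x in active if x not in (i, j)] + [new]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        for idx, bl in zip((i, j, k), (bi, bj, bk)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = max(bl, 0.0)
    else:  # 2 remaining clusters (cannot happen for n >= 3 input, kept for safety)
        i, j = active
        root.add_child(nodes[i])
        root.add_child(nodes[j])
        nodes[i].edge.length = nodes[j].edge.length = D[i, j] / 2
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# likelihood engine (Felsenstein pruning)


def _encode_patterns(alignment: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Site-pattern compression: (n_taxa, n_patterns) int8 codes and counts.

    Gaps and ambiguity codes become -1 (missing: partial likelihood 1 for
    every state).
    """
    L = alignment.n_columns
    codes = np.full((alignment.n_taxa, L), -1, dtype=np.int8)
    for r, row in enumerate(alignment.rows):
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for b, i in STATE_INDEX.items():
            codes[r, arr == ord(b)] = i
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class LikelihoodEngine:
    """Felsenstein pruning over a fixed topology with mutable branch lengths."""

    def __init__(
        self,
        tree: dendropy.Tree,
        alignment: MultipleAlignment,
        model: SubstitutionModel,
    ):
        if alignment.n_columns == 0:
            raise ValueError("zero-length alignment")
        model = model.resolved(empirical_base_freqs(alignment.rows))
        self.model = model
        self.probs = TransitionProbabilities(model)
        self.patterns, self.counts = _encode_patterns(alignment)
        taxon_row = {t: i for i, t in enumerate(alignment.taxa)}

        self.tree = tree
        self.nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(self.nodes)}
        leaf_labels = {nd.taxon.label for nd in tree.leaf_node_iter()}
        if leaf_labels != set(alignment.taxa):
            raise ValueError("tree leaves do not match alignment taxa")

        self.children: list[list[int]] = []
        self.leaf_row: list[int | None] = []
        lengths = []
        self.edge_of_node: list[int | None] = []
        for nd in self.nodes:
            kids = [index[id(c)] for c in nd.child_nodes()]
            self.children.append(kids)
            self.leaf_row.append(taxon_row[nd.taxon.label] if nd.is_leaf() else None)
            if nd is tree.seed_node:
                self.edge_of_node.append(None)
            else:
                self.edge_of_node.append(len(lengths))
                lengths.append(nd.edge.length if nd.edge.length else 1e-8)
        self.lengths = np.asarray(lengths, dtype=float)
        self._P = self.probs(self.lengths)  # cached per-edge transition matrices

        npat = self.patterns.shape[1]
        self._leaf_partials: dict[int, np.ndarray] = {}
        for i, row in enumerate(self.leaf_row):
            if row is None:
                continue
            part = np.ones((npat, 4))
            codes = self.patterns[row]
            known = codes >= 0
            part[known] = 0.0
            part[np.nonzero(known)[0], codes[known]] = 1.0
            self._leaf_partials[i] = part

    def set_branch(self, edge_idx: int, length: float) -> None:
        self.lengths[edge_idx] = length
        self._P[edge_idx] = self.probs(float(length))

    def write_back(self) -> None:
        """Copy current branch lengths onto the dendropy tree."""
        for i, nd in enumerate(self.nodes):
            e = self.edge_of_node[i]
            if e is not None:
                nd.edge.length = float(self.lengths[e])

    def loglik(self) -> float:
        P = self._P  # (n_edges, 4, 4)
        partials: list[np.ndarray | None] = [None] * len(self.nodes)
        for i, kids in enumerate(self.children):
            if not kids:
                partials[i] = self._leaf_partials[i]
                continue
            acc = None
            for c in kids:
                term = partials[c] @ P[self.edge_of_node[c]].T
                acc = term if acc is None else acc * term
            partials[i] = acc
        site_lik = partials[-1] @ self.model.base_freqs
        return float(np.sum(self.counts * np.log(np.maximum(site_lik, 1e-300))))

    def optimize_branch_lengths(
        self,
        tol: float = 1e-4,
        max_cycles: int = 20,
        max_length: float = 10.0,
        xatol: float = 1e-6,
    ) -> float:
        """Cyclic one-dimensional optimization; monotone non-decreasing."""
        current = self.loglik()
        lo, hi = math.log(1e-9), math.log(max_length)
        for _ in range(max_cycles):
            cycle_start = current
            for e in range(len(self.lengths)):
                old = self.lengths[e]

                def neg(u: float, e: int = e) -> float:
                    self.set_branch(e, math.exp(min(max(u, lo), hi)))
                    return -self.loglik()

                u0 = math.log(max(old, 1e-8))
                try:
                    res = minimize_scalar(
                        neg,
                        bracket=(u0 - 0.7, u0, u0 + 0.7),
                        method="brent",
                        options={"xtol": max(xatol, 1e-6) * 10},
                    )
                except ValueError:  # bracketing failed on a flat/edge profile
                    res = minimize_scalar(
                        neg, bounds=(lo, hi), method="bounded",
                        options={"xatol": max(xatol, 1e-6) * 10},
                    )
                if -res.fun >= current:
                    self.set_branch(e, math.exp(min(max(float(res.x), lo), hi)))
                    current = -res.fun
                else:  # guard against optimizer regression
                    self.set_branch(e, old)
            if current - cycle_start < tol:
                break
        else:
            logger.debug(
                "branch-length optimization stopped at max_cycles=%d", max_cycles
            )
        self.write_back()
        return current

    def optimize_kappa(self, bounds: tuple[float, float] = (0.05, 100.0)) -> float:
        """ML estimate of kappa on the current tree (Brent, bounded)."""
        if self.model.name == "JC69":
            return 1.0
        old_kappa = self.model.kappa
        current = self.loglik()

        def neg(kappa: float) -> float:
            self.model.kappa = kappa
            self.probs = TransitionProbabilities(self.model)
            self._P = self.probs(self.lengths)
            return -self.loglik()

        res = minimize_scalar(neg, bounds=bounds, method="bounded",
                              options={"xatol": 1e-4})
        if -res.fun >= current:
            neg(float(res.x))  # leave engine at the optimum
            return float(res.x)
        neg(old_kappa)  # keep the starting value if the optimizer regressed
        return old_kappa


def loglik(
    tree: dendropy.Tree, alignment: MultipleAlignment, model: SubstitutionModel
) -> float:
    """Log-likelihood of ``alignment`` on ``tree`` (branch lengths as given)."""
    return LikelihoodEngine(tree, alignment, model).loglik()


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: MultipleAlignment,
    model: SubstitutionModel,
    tol: float = 1e-4,
) -> tuple[dendropy.Tree, float]:
    engine = LikelihoodEngine(tree, alignment, model)
    ll = engine.optimize_branch_lengths(tol=tol)
    return tree, ll


# ---------------------------------------------------------------------------
# bootstrap and tree comparison


def _internal_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as frozensets of leaf labels (smaller-side free)."""
    all_leaves = frozenset(nd.taxon.label for nd in tree.leaf_node_iter())
    splits = set()
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def bootstrap_support(
    alignment: MultipleAlignment,
    model: SubstitutionModel,
    B: int = 100,
    seed: int | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ point tree with nonparametric bootstrap supports.

    Supports are fractions of ``B`` column resamples whose NJ tree contains
    the same bipartition. With zero variable columns no bipartition is
    resolvable and every support is reported as NaN.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if alignment.n_taxa < 4:
        raise ValueError("bootstrap needs >= 4 taxa")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    point = nj_tree(pairwise_distance(alignment, model))

    cols = np.array([list(r) for r in alignment.rows])
    L = alignment.n_columns
    informative = any(len(set(cols[:, j])) > 1 for j in range(L))

    counts: dict[frozenset[str], int] = {s: 0 for s in _internal_bipartitions(point)}
    if informative:
        for _ in range(B):
            idx = rng.integers(0, L, size=L)
            res_rows = ["".join(row) for row in cols[:, idx]]
            rep = nj_tree(
                pairwise_distance(
                    MultipleAlignment(list(alignment.taxa), res_rows, alignment.type),
                    model,
                )
            )
            for s in _internal_bipartitions(rep):
                if s in counts:
                    counts[s] += 1
        supports = {s: c / B for s, c in counts.items()}
    else:
        supports = {s: float("nan") for s in counts}

    # annotate internal nodes for newick output
    all_leaves = frozenset(alignment.taxa)
    for nd in point.preorder_internal_node_iter():
        if nd is point.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
        if key in supports:
            v = supports[key]
            nd.label = "NA" if math.isnan(v) else str(int(round(v * B)))
    return point, supports


def rf_distance(tree1: dendropy.Tree, tree2: dendropy.Tree) -> int:
    """Unweighted Robinson–Foulds distance (bipartition symmetric difference)."""
    leaves1 = {nd.taxon.label for nd in tree1.leaf_node_iter()}
    leaves2 = {nd.taxon.label for nd in tree2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(f"leaf sets differ: {sorted(leaves1 ^ leaves2)}")
    s1, s2 = _internal_bipartitions(tree1), _internal_bipartitions(tree2)
    return len(s1 ^ s2)


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, schema="newick")
    return dendropy.Tree.get(path=src, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
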