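"""Single-breakpoint recombination scan by information-criterion model choice.

A recombinant alignment is one whose true genealogy switches topology at
some column. The scan asks, for every candidate breakpoint on a stride
grid, whether two phylogenies fitted independently to the left and right
sub-alignments explain the data enough better than one phylogeny fitted
to the whole alignment to justify their extra parameters, judged by the
small-sample Akaike criterion AICc = 2k - 2lnL + 2k(k+1)/(n-k-1).

Trees come from neighbor joining on model distances with ML branch
lengths (and kappa, for K80/HKY85) refined on the fixed topology. Each
segment fit additionally evaluates the whole-alignment topology seeded
from the single fit's branch lengths and keeps the better of the two,
which guarantees the nesting property lnL_left + lnL_right >= lnL_single
at every candidate. The scan is exhaustive on its grid and fully
deterministic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .models import SubstitutionModel
from .phylo import (
    LikelihoodEngine,
    MultipleAlignment,
    nj_tree,
    pairwise_distance,
)

logger = logging.getLogger(__name__)


@dataclass
class SBPParams:
    min_segment: int = 200
    stride: int = 10
    model: SubstitutionModel = field(default_factory=lambda: SubstitutionModel("HKY85"))
    delta_aicc_threshold: float = 10.0
    #: AICc sample size: "columns" (total alignment columns) or "variable"
    sample_size: str = "columns"

    def __post_init__(self) -> None:
        if self.min_segment < 4:
            raise ValueError("min_segment must be >= 4")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.sample_size not in ("columns", "variable"):
            raise ValueError("sample_size must be 'columns' or 'variable'")


@dataclass
class TreeFit:
    tree: dendropy.Tree
    lnl: float
    k_params: int
    kappa: float


@dataclass
class BreakpointCandidate:
    position: int  # breakpoint falls after this alignment column
    lnl_left: float
    lnl_right: float
    aicc_two: float
    delta_aicc: float


@dataclass
class SBPResult:
    aicc_single: float
    lnl_single: float
    candidates: list[BreakpointCandidate]
    best: BreakpointCandidate | None
    verdict: str  # "breakpoint" | "none"

    def write_profile_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tlnl_left\tlnl_right\tdelta_aicc\n")
            for c in self.candidates:
                fh.write(
                    f"{c.position}\t{c.lnl_left:.4f}\t{c.lnl_right:.4f}\t{c.delta_aicc:.4f}\n"
                )

    def write_json(self, path: str | Path) -> None:
        payload = {
            "verdict": self.verdict,
            "aicc_single": self.aicc_single,
            "lnl_single": self.lnl_single,
            "best_position": self.best.position if self.best else None,
            "best_delta_aicc": self.best.delta_aicc if self.best else None,
            "n_candidates": len(self.candidates),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def single_tree_fit(
    alignment: MultipleAlignment,
    model: SubstitutionModel,
    start_tree: dendropy.Tree | None = None,
) -> TreeFit:
    """NJ topology (or a supplied one) with ML branch lengths and kappa.

    The parameter count is (2n - 3) branch lengths plus one for kappa under
    K80/HKY85 (HKY85 base frequencies are empirical, hence not counted).
    """
    if alignment.n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    tree = start_tree or nj_tree(pairwise_distance(alignment, model))
    engine = LikelihoodEngine(tree, alignment, model)
    # lnL tolerance 0.01 is ample against a delta-AICc threshold of 10
    engine.optimize_branch_lengths(tol=1e-2, max_cycles=6, xatol=1e-4)
    if model.name != "JC69":
        engine.optimize_kappa()
        lnl = engine.optimize_branch_lengths(tol=1e-2, max_cycles=6, xatol=1e-4)
    else:
        lnl = engine.loglik()
    engine.write_back()
    k = 2 * alignment.n_taxa - 3 + model.n_free_params
    return TreeFit(tree=tree, lnl=lnl, k_params=k, kappa=engine.model.kappa)


def _clone_with_lengths(fit: TreeFit) -> dendropy.Tree:
    return fit.tree.clone(depth=1)


def _segment_fit(
    segment: MultipleAlignment, model: SubstitutionModel, single: TreeFit
) -> TreeFit:
    """Best of (segment NJ topology, whole-data topology warm-started).

    When the segment's own NJ topology coincides with the whole-data
    topology only the warm-started fit is run (they would optimize the
    same tree).
    """
    from .phylo import _internal_bipartitions

    warm = single_tree_fit(
        segment,
        SubstitutionModel(model.name, single.kappa),
        start_tree=_clone_with_lengths(single),
    )
    own_topology = nj_tree(
        pairwise_distance(segment, SubstitutionModel(model.name, model.kappa))
    )
    if _internal_bipartitions(own_topology) == _internal_bipartitions(single.tree):
        return warm
    own = single_tree_fit(
        segment, SubstitutionModel(model.name, model.kappa), start_tree=own_topology
    )
    return own if own.lnl >= warm.lnl else warm


def _n_variable_columns(alignment: MultipleAlignment) -> int:
    cols = np.array([list(r) for r in alignment.rows])
    return int(sum(len(set(cols[:, j])) > 1 for j in range(alignment.n_columns)))


def sbp_scan(alignment: MultipleAlignment, params: SBPParams | None = None) -> SBPResult:
    """Scan every stride-grid column for a single recombination breakpoint.

    Candidates are columns p with ``min_segment <= p <= L - min_segment``
    (breakpoint after column p). The verdict is ``breakpoint`` when the
    best candidate improves AICc by at least ``delta_aicc_threshold``;
    ties in delta-AICc break toward the smaller position.
    """
    params = params or SBPParams()
    L = alignment.n_columns
    if L < 2 * params.min_segment:
        raise ValueError(
            f"alignment length {L} < 2 x min_segment {params.min_segment}"
        )
    model = params.model
    single = single_tree_fit(alignment, SubstitutionModel(model.name, model.kappa))
    n = L if params.sample_size == "columns" else _n_variable_columns(alignment)
    aicc_single = aicc(single.lnl, single.k_params, n)

    candidates: list[BreakpointCandidate] = []
    positions = range(params.min_segment, L - params.min_segment + 1, params.stride)
    for p in positions:
        left = alignment.subset_columns(1, p)
        right = alignment.subset_columns(p + 1, L)
        fit_l = _segment_fit(left, model, single)
        fit_r = _segment_fit(right, model, single)
        k_two = fit_l.k_params + fit_r.k_params
        if n - k_two - 1 <= 0:
            warnings.warn(f"candidate {p} skipped: AICc undefined (n={n}, k={k_two})")
            continue
        a2 = aicc(fit_l.lnl + fit_r.lnl, k_two, n)
        candidates.append(
            BreakpointCandidate(
                position=p,
                lnl_left=fit_l.lnl,
                lnl_right=fit_r.lnl,
                aicc_two=a2,
                delta_aicc=aicc_single - a2,
            )
        )

    best = None
    for c in candidates:  # first (= smallest position) wins ties
        if best is None or c.delta_aicc > best.delta_aicc + 1e-9:
            best = c
    verdict = (
        "breakpoint"
        if best is not None and best.delta_aicc >= params.delta_aicc_threshold
        else "none"
    )
    return SBPResult(
        aicc_single=aicc_single,
        lnl_single=single.lnl,
        candidates=candidates,
        best=best,
        verdict=verdict,
    )


def plot_profile(result: SBPResult, path: str | Path | None = None):
    """Delta-AICc profile over candidate breakpoints."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 2.5))
    x = [c.position for c in result.candidates]
    y = [c.delta_aicc for c in result.candidates]
    ax.plot(x, y, lw=1)
    ax.axhline(0, color="k", lw=0.5)
    if result.best is not None:
        ax.axvline(result.best.position, color="firebrick", ls="--", lw=0.8)
    ax.set_xlabel("alignment column")
    ax.set_ylabel(r"$\Delta$AICc")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
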