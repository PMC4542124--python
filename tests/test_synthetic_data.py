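import math

import numpy as np
import pytest

from mosaictox.models import STATE_INDEX, SubstitutionModel
from mosaictox.seq_core import gc_fraction
from mosaictox.synthetic_data import (
    IslandSpec,
    SimTruth,
    evolve_alignment,
    mosaic_locus_pair,
    simulate_annotation,
    simulate_genome,
    simulate_recombinant,
)


def binomial_bound(p: float, n: int, z: float = 4.0) -> float:
    return z * math.sqrt(p * (1 - p) / n)


class TestSimulateGenome:
    def test_background_composition_within_binomial_bound(self):
        g, _ = simulate_genome(100_000, 0.60, [], seed=5)
        assert abs(gc_fraction(g.sequence) - 0.60) < binomial_bound(0.6, 100_000)

    def test_island_composition_within_bound(self):
        g, truth = simulate_genome(
            200_000, 0.60, [IslandSpec(50_001, 20_000, 0.45)], seed=6
        )
        isl = truth.truth["islands"][0]
        island_seq = g.sequence[isl["start"] - 1 : isl["end"]]
        assert abs(gc_fraction(island_seq) - 0.45) < binomial_bound(0.45, 20_000)

    def test_fixed_seed_byte_identical(self):
        g1, _ = simulate_genome(10_000, 0.5, [], seed=9)
        g2, _ = simulate_genome(10_000, 0.5, [], seed=9)
        assert g1.sequence == g2.sequence

    def test_overlapping_islands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_genome(
                10_000, 0.5,
                [IslandSpec(100, 500, 0.4), IslandSpec(400, 500, 0.7)],
                seed=1,
            )

    def test_truth_roundtrip(self, tmp_path):
        _, truth = simulate_genome(
            10_000, 0.5, [IslandSpec(1_000, 2_000, 0.3)], seed=2
        )
        p = tmp_path / "truth.json"
        truth.write_json(p)
        back = SimTruth.read_json(p)
        assert back.truth == truth.truth and back.seed == truth.seed


class TestSimulateAnnotation:
    def test_focal_percentile_matches_enumeration(self):
        base, _ = simulate_genome(1_200_000, 0.44, [], seed=40)
        genome, feats, truth = simulate_annotation(
            base, 999, gene_length_range=(600, 900), focal_gene_gc_offset=0.12, seed=41
        )
        from mosaictox.gene_gc_stats import gc_percentile, gene_gc_table

        recs = gene_gc_table(genome, feats)
        focal = truth.truth["focal_id"]
        gcs = truth.truth["per_gene_gc"]
        expected = sum(
            1 for k, v in gcs.items() if k != focal and v >= gcs[focal]
        ) / 998
        assert gc_percentile(recs, focal) == expected

    def test_zero_offset_percentile_roughly_uniform(self):
        """Unshifted focal gene ranks uniformly among its peers."""
        fracs = []
        for s in range(30):
            base, _ = simulate_genome(80_000, 0.44, [], seed=500 + s)
            genome, feats, truth = simulate_annotation(
                base, 50, focal_gene_gc_offset=0.0, seed=600 + s
            )
            from mosaictox.gene_gc_stats import gc_percentile, gene_gc_table

            fracs.append(
                gc_percentile(gene_gc_table(genome, feats), truth.truth["focal_id"])
            )
        assert 0.35 < np.mean(fracs) < 0.65

    def test_infeasible_packing_raises(self):
        base, _ = simulate_genome(5_000, 0.5, [], seed=1)
        with pytest.raises(ValueError, match="pack"):
            simulate_annotation(base, 100, seed=2)


class TestEvolveAlignment:
    def test_zero_branch_lengths_identical_rows(self):
        aln, _ = evolve_alignment(
            "((A:0,B:0):0,(C:0,D:0):0);", SubstitutionModel("JC69"), 200, seed=3
        )
        assert len(set(aln.rows)) == 1

    def test_two_taxon_p_distance_closed_form(self):
        aln, _ = evolve_alignment(
            "(x:0.1,y:0.1);", SubstitutionModel("JC69"), 100_000, seed=4
        )
        p = sum(a != b for a, b in zip(*aln.rows)) / 100_000
        expected = 0.75 * (1 - math.exp(-4 * 0.2 / 3))
        assert abs(p - expected) < 0.005

    def test_kappa_biases_transitions(self):
        aln, _ = evolve_alignment(
            "(x:0.15,y:0.15);", SubstitutionModel("HKY85", kappa=4.0), 50_000, seed=5
        )
        ts = tv = 0
        purines = {"A", "G"}
        for a, b in zip(*aln.rows):
            if a == b:
                continue
            if (a in purines) == (b in purines):
                ts += 1
            else:
                tv += 1
        assert ts / tv > 1.5

    def test_determinism(self):
        a1, _ = evolve_alignment("(x:0.1,y:0.1);", SubstitutionModel("JC69"), 500, seed=6)
        a2, _ = evolve_alignment("(x:0.1,y:0.1);", SubstitutionModel("JC69"), 500, seed=6)
        assert a1.rows == a2.rows


class TestSimulateRecombinant:
    def test_truth_records_breakpoint_and_trees(self):
        aln, truth = simulate_recombinant(
            "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);",
            "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);",
            300, SubstitutionModel("JC69"), 1000, seed=7,
        )
        assert aln.n_columns == 1000
        assert truth.truth["breakpoint_column"] == 300
        assert "newick_left" in truth.truth

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf sets"):
            simulate_recombinant(
                "((A:1,B:1):1,(C:1,D:1));", "((A:1,B:1):1,(C:1,E:1));",
                10, SubstitutionModel("JC69"), 100, seed=8,
            )

    def test_identical_trees_scan_verdict_none(self, balanced_tree):
        """Same tree on both sides carries no recombination signal."""
        from mosaictox.breakpoint_scan import SBPParams, sbp_scan

        aln, _ = simulate_recombinant(
            balanced_tree, balanced_tree, 600,
            SubstitutionModel("HKY85", kappa=4.0), 1200, seed=9,
        )
        res = sbp_scan(aln, SBPParams(model=SubstitutionModel("JC69"), stride=50))
        assert res.verdict == "none"


class TestMosaicLocusPair:
    def test_segment_divergence_realized(self):
        ref, qry, truth = mosaic_locus_pair([(4000, 0.10), (4000, 0.60)], seed=10)
        seg = truth.truth["segments"]
        d0 = sum(a != b for a, b in zip(ref[:4000], qry[:4000])) / 4000
        d1 = sum(a != b for a, b in zip(ref[4000:], qry[4000:])) / 4000
        assert abs(d0 - 0.10) < binomial_bound(0.10, 4000)
        assert abs(d1 - 0.60) < binomial_bound(0.60, 4000)
        assert seg[1]["start"] == 4001

    def test_seed_required_everywhere(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_genome(1000, 0.5, [])
        with pytest.raises(ValueError, match="seed"):
            mosaic_locus_pair([(100, 0.1)])
        with pytest.raises(ValueError, match="seed"):
            evolve_alignment("(a:0.1,b:0.1);", SubstitutionModel("JC69"), 10)
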