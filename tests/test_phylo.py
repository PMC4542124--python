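import itertools
import math

import dendropy
import numpy as np
import pytest

from mosaictox.models import (
    STATE_INDEX,
    SubstitutionModel,
    TransitionProbabilities,
    rate_matrix,
)
from mosaictox.phylo import (
    BlockFilterParams,
    DistanceMatrix,
    LikelihoodEngine,
    MultipleAlignment,
    block_filter,
    bootstrap_support,
    concat_alignments,
    loglik,
    nj_tree,
    optimize_branch_lengths,
    pairwise_distance,
    read_newick,
    rf_distance,
)
from mosaictox.synthetic_data import evolve_alignment


class TestModels:
    def test_rows_of_p_sum_to_one(self):
        probs = TransitionProbabilities(SubstitutionModel("HKY85", 3.0, [0.3, 0.2, 0.3, 0.2]))
        for t in (0.01, 0.1, 1.0, 5.0):
            assert np.allclose(probs(t).sum(axis=1), 1.0)

    def test_stationarity(self):
        pi = np.array([0.4, 0.1, 0.3, 0.2])
        probs = TransitionProbabilities(SubstitutionModel("HKY85", 2.5, pi))
        assert np.allclose(pi @ probs(0.7), pi)

    def test_rate_normalization(self):
        m = SubstitutionModel("K80", kappa=5.0)
        Q = rate_matrix(m)
        assert -(m.base_freqs * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_jc_closed_form_p_at_t(self):
        # JC69: P(change) = 3/4 (1 - e^{-4t/3})
        probs = TransitionProbabilities(SubstitutionModel("JC69"))
        t = 0.3
        p_off = 1 - probs(t)[0, 0]
        assert p_off == pytest.approx(0.75 * (1 - math.exp(-4 * t / 3)), abs=1e-12)


class TestConcat:
    def test_published_fragment_lengths(self):
        """recA (537) + rpoB (508) + rpoD (695) concatenate to 1740 columns."""
        taxa = ["t1", "t2", "t3"]
        alns = [
            MultipleAlignment(taxa, ["A" * n] * 3) for n in (537, 508, 695)
        ]
        combined = concat_alignments(alns)
        assert combined.n_columns == 1740
        assert combined.partitions[-1] == ("partition_3", 1046, 1740)

    def test_single_input_identity(self):
        a = MultipleAlignment(["x", "y", "z"], ["ACGT"] * 3)
        assert concat_alignments([a]).rows == a.rows

    def test_taxon_order_insensitive(self):
        a1 = MultipleAlignment(["b", "a"], ["CC", "AA"])
        a2 = MultipleAlignment(["a", "b"], ["TT", "GG"])
        combined = concat_alignments([a1, a2])
        assert combined.taxa == ["a", "b"]
        assert combined.rows == ["AATT", "CCGG"]

    def test_taxon_mismatch_lists_offenders(self):
        a1 = MultipleAlignment(["a", "b"], ["AC", "GT"])
        a2 = MultipleAlignment(["a", "c"], ["AC", "GT"])
        with pytest.raises(ValueError, match="c"):
            concat_alignments([a1, a2])


class TestBlockFilter:
    def test_identical_gapfree_alignment_keeps_all(self):
        a = MultipleAlignment(["a", "b", "c", "d"], ["ACGTACGTACGTACG"] * 4)
        filtered, kept = block_filter(a)
        assert kept == list(range(1, 16))
        assert filtered.rows == a.rows

    def test_nonconserved_block_removed_flanks_kept(self):
        """A 12-column all-different block between conserved flanks is cut."""
        flank = "ACGTACGTACGTACG"  # 15 conserved columns
        rows = [
            flank + "AAAAAAAAAAAA" + flank,
            flank + "CCCCCCCCCCCC" + flank,
            flank + "GGGGGGGGGGGG" + flank,
            flank + "TTTTTTTTTTTT" + flank,
        ]
        filtered, kept = block_filter(MultipleAlignment(list("abcd"), rows))
        assert filtered.n_columns == 30
        assert kept == list(range(1, 16)) + list(range(28, 43))

    def test_any_gap_column_removed_with_allow_gaps_none(self):
        rows = ["ACGTAAACGTACGTA", "AC-TAAACGTACGTA", "ACGTAAACGTACGTA", "ACGTAAACGTACGTA"]
        filtered, kept = block_filter(MultipleAlignment(list("abcd"), rows))
        assert 3 not in kept
        assert "-" not in "".join(filtered.rows)

    def test_short_surviving_block_dropped(self):
        rows = ["ACGTA" + "-" * 3 + "ACGTACGTACGTA"] * 4
        filtered, kept = block_filter(MultipleAlignment(list("wxyz"), rows))
        # 5-column left block < min_block_length 10 is dropped
        assert min(kept) == 9

    def test_all_removed_warns_not_raises(self):
        rows = ["A-", "C-", "G-", "T-"]
        with pytest.warns(UserWarning, match="every column"):
            filtered, kept = block_filter(MultipleAlignment(list("abcd"), rows))
        assert kept == [] and filtered.n_columns == 0


class TestDistances:
    def test_identical_rows_zero(self):
        a = MultipleAlignment(["x", "y"], ["ACGTACGT", "ACGTACGT"])
        assert pairwise_distance(a, SubstitutionModel("JC69")).matrix[0, 1] == 0.0

    def test_jc69_closed_form(self):
        a = MultipleAlignment(["x", "y"], ["A" * 900 + "C" * 100, "A" * 900 + "G" * 100])
        d = pairwise_distance(a, SubstitutionModel("JC69")).matrix[0, 1]
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-9)
        assert round(d, 5) == 0.10733

    def test_saturation_capped_with_warning(self):
        a = MultipleAlignment(["x", "y"], ["AAAA" * 50, "CCCC" * 50])
        with pytest.warns(UserWarning, match="capping"):
            d = pairwise_distance(a, SubstitutionModel("JC69")).matrix[0, 1]
        assert d == 5.0

    def test_k80_recovers_simulated_distance(self):
        aln, _ = evolve_alignment(
            "(x:0.1,y:0.1);", SubstitutionModel("K80", kappa=4.0), 50_000, seed=5
        )
        d = pairwise_distance(aln, SubstitutionModel("K80")).matrix[0, 1]
        assert d == pytest.approx(0.2, abs=0.01)

    def test_hky_parameter_recovery_over_seeds(self):
        """Mean pairwise-ML HKY85 distance near truth across replicates."""
        est = []
        for s in range(12):
            aln, _ = evolve_alignment(
                "(x:0.1,y:0.1);",
                SubstitutionModel("HKY85", kappa=4.0, base_freqs=[0.3, 0.2, 0.3, 0.2]),
                10_000,
                seed=700 + s,
            )
            est.append(
                pairwise_distance(aln, SubstitutionModel("HKY85", kappa=4.0)).matrix[0, 1]
            )
        assert np.mean(est) == pytest.approx(0.2, abs=0.01)

    def test_protein_poisson(self):
        a = MultipleAlignment(["x", "y"], ["MKLV" * 25, "MKLV" * 20 + "MKIV" * 5], "protein")
        p = 5 / 100
        d = pairwise_distance(a, SubstitutionModel("JC69")).matrix[0, 1]
        assert d == pytest.approx(-math.log(1 - p))


class TestNJ:
    def test_exact_on_additive_matrix(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        taxa = list("ABCD")
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(taxa, D))
        ref = read_newick("((A:1,B:2):1,(C:3,D:4));")
        assert rf_distance(tree, ref) == 0
        pdm = tree.phylogenetic_distance_matrix()
        t = {x.label: x for x in tree.taxon_namespace}
        for (i, j), expect in {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }.items():
            assert pdm.patristic_distance(t[i], t[j]) == pytest.approx(expect)

    def test_three_taxa_star(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABC"), D))
        lengths = {
            nd.taxon.label: nd.edge.length for nd in tree.leaf_node_iter()
        }
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    def test_deterministic_under_ties(self):
        D = np.ones((4, 4)) - np.eye(4)
        results = {
            nj_tree(DistanceMatrix(list("ABCD"), D.copy())).as_string(schema="newick")
            for _ in range(3)
        }
        assert len(results) == 1

    def test_agrees_with_independent_nj_oracle(self):
        """Topology matches dendropy's own NJ on a noisy matrix."""
        rng = np.random.default_rng(42)
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.1, 1.0, (n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        mine = nj_tree(DistanceMatrix(taxa, D))
        csv = "," + ",".join(taxa) + "\n" + "\n".join(
            taxa[i] + "," + ",".join(str(D[i, j]) for j in range(n)) for i in range(n)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        oracle = pdm.nj_tree()
        oracle2 = dendropy.Tree.get(
            data=oracle.as_string(schema="newick"), schema="newick"
        )
        assert rf_distance(mine, oracle2) == 0

    def test_rejects_asymmetric_matrix(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("ABC"), D)


def _brute_force_loglik(tree, aln, model):
    """Enumerate all internal-node state assignments per site."""
    tree = dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick")
    model = model.resolved(np.full(4, 0.25))
    probs = TransitionProbabilities(model)
    internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    rows = {t: r for t, r in zip(aln.taxa, aln.rows)}
    total = 0.0
    for site in range(aln.n_columns):
        site_lik = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = {id(nd): s for nd, s in zip(internals, states)}
            for lf in leaves:
                assign[id(lf)] = STATE_INDEX[rows[lf.taxon.label][site]]
            p = model.base_freqs[assign[id(tree.seed_node)]]
            for nd in tree.preorder_node_iter():
                if nd is tree.seed_node:
                    continue
                P = probs(nd.edge.length or 0.0)
                p *= P[assign[id(nd.parent_node)], assign[id(nd)]]
            site_lik += p
        total += math.log(site_lik)
    return total


class TestLikelihood:
    def test_matches_brute_force_enumeration_star(self):
        tree = read_newick("(A:0.1,B:0.1,C:0.1);")
        aln = MultipleAlignment(list("ABC"), ["AC", "AG", "CT"])
        model = SubstitutionModel("JC69")
        assert loglik(tree, aln, model) == pytest.approx(
            _brute_force_loglik(tree, aln, model), abs=1e-10
        )

    def test_matches_brute_force_two_internal_nodes(self):
        tree = read_newick("((A:0.2,B:0.05):0.1,C:0.3,D:0.15);")
        aln = MultipleAlignment(list("ABCD"), ["ACGT", "AGGT", "CCGA", "ACTT"])
        for model in (SubstitutionModel("JC69"), SubstitutionModel("K80", kappa=3.0)):
            assert loglik(tree, aln, model) == pytest.approx(
                _brute_force_loglik(tree, aln, model), abs=1e-10
            )

    def test_zero_branch_limit_identical_sequences(self):
        tree = read_newick("(A:0.0,B:0.0,C:0.0);")
        aln = MultipleAlignment(list("ABC"), ["AAAA", "AAAA", "AAAA"])
        ll = loglik(tree, aln, SubstitutionModel("JC69"))
        assert ll == pytest.approx(4 * math.log(0.25), abs=1e-6)

    def test_duplicated_columns_double_loglik(self):
        tree = read_newick("(A:0.1,B:0.2,C:0.3);")
        aln1 = MultipleAlignment(list("ABC"), ["ACG", "AGG", "CCT"])
        aln2 = MultipleAlignment(list("ABC"), ["ACGACG", "AGGAGG", "CCTCCT"])
        m = SubstitutionModel("HKY85", base_freqs=[0.25, 0.25, 0.25, 0.25])
        assert loglik(tree, aln2, m) == pytest.approx(2 * loglik(tree, aln1, m))

    def test_gaps_treated_as_missing(self):
        tree = read_newick("(A:0.1,B:0.2,C:0.3);")
        full = MultipleAlignment(list("ABC"), ["A", "G", "-"])
        # marginalizing C out: likelihood equals 2-taxon A-B path
        two = MultipleAlignment(list("AB"), ["A", "G"])
        probs = TransitionProbabilities(SubstitutionModel("JC69"))
        p_ab = 0.25 * probs(0.3)[0, 2]  # t = 0.1 + 0.2, A->G
        assert math.exp(loglik(tree, full, SubstitutionModel("JC69"))) == pytest.approx(
            p_ab
        )


class TestOptimizeBranchLengths:
    def test_two_taxon_equals_jc_distance(self):
        aln = MultipleAlignment(
            ["x", "y"], ["A" * 900 + "C" * 100, "A" * 900 + "G" * 100]
        )
        tree = read_newick("(x:0.05,y:0.05);")
        tree, ll = optimize_branch_lengths(tree, aln, SubstitutionModel("JC69"))
        total = sum(nd.edge.length for nd in tree.leaf_node_iter())
        assert total == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-4)

    def test_monotone_never_decreases(self, balanced_tree, hky):
        aln, _ = evolve_alignment(balanced_tree, hky, 800, seed=19)
        tree = read_newick("((A:0.5,B:0.01):0.3,(C:0.02,D:0.4):0.2);")
        start = loglik(tree, aln, hky)
        _, final = optimize_branch_lengths(tree, aln, hky)
        assert final >= start

    def test_recovers_lengths_at_large_n(self, balanced_tree, hky):
        aln, _ = evolve_alignment(balanced_tree, hky, 10_000, seed=29)
        tree = read_newick("((A:0.3,B:0.02):0.15,(C:0.25,D:0.01):0.05);")
        tree, _ = optimize_branch_lengths(tree, aln, hky)
        for nd in tree.leaf_node_iter():
            assert nd.edge.length == pytest.approx(0.1, rel=0.10, abs=0.01)


class TestBootstrapAndRF:
    def test_strong_signal_high_support(self, balanced_tree):
        aln, _ = evolve_alignment(
            balanced_tree, SubstitutionModel("HKY85", kappa=4.0), 5_000, seed=47
        )
        tree, supports = bootstrap_support(aln, SubstitutionModel("K80"), B=100, seed=7)
        (support,) = [v for k, v in supports.items() if k == frozenset("AB")]
        assert support >= 0.95

    def test_fixed_seed_reproducible(self, balanced_tree, hky):
        aln, _ = evolve_alignment(balanced_tree, hky, 1_000, seed=53)
        _, s1 = bootstrap_support(aln, SubstitutionModel("JC69"), B=20, seed=3)
        _, s2 = bootstrap_support(aln, SubstitutionModel("JC69"), B=20, seed=3)
        assert s1 == s2

    def test_identical_sequences_supports_na(self):
        aln = MultipleAlignment(list("ABCD"), ["ACGTACGT"] * 4)
        _, supports = bootstrap_support(aln, SubstitutionModel("JC69"), B=10, seed=1)
        assert all(math.isnan(v) for v in supports.values())

    def test_seed_required(self, balanced_tree, hky):
        aln, _ = evolve_alignment(balanced_tree, hky, 100, seed=1)
        with pytest.raises(ValueError, match="seed"):
            bootstrap_support(aln, SubstitutionModel("JC69"), B=10)

    def test_rf_identity_and_conflict(self, balanced_tree, conflicting_tree):
        t1 = read_newick(balanced_tree)
        t2 = read_newick(conflicting_tree)
        assert rf_distance(t1, t1) == 0
        assert rf_distance(t1, t2) == 2

    def test_rf_bound_random_trees(self):
        rng = np.random.default_rng(0)
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        for s in range(5):
            t1 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
                num_extant_tips=8, rng=__import__("random").Random(s),
            )
            t2 = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
                num_extant_tips=8, rng=__import__("random").Random(100 + s),
            )
            assert rf_distance(t1, t2) <= 2 * (8 - 3)

    def test_rf_leaf_mismatch_raises(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1));")
        t2 = read_newick("((A:1,B:1):1,(C:1,E:1));")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)


class TestNJTopologyRecovery:
    def test_recovery_rate_on_simulations(self):
        """NJ finds the true 5-taxon topology in >= 19/20 replicates."""
        newick = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05,E:0.15);"
        truth = read_newick(newick)
        hit = 0
        for s in range(20):
            aln, _ = evolve_alignment(
                newick, SubstitutionModel("HKY85", kappa=2.0), 5_000, seed=900 + s
            )
            tree = nj_tree(pairwise_distance(aln, SubstitutionModel("K80")))
            if rf_distance(tree, truth) == 0:
                hit += 1
        assert hit >= 19
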