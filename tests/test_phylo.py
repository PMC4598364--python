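"""Trees, parsimony ancestral states, consensus, and Mantel tests."""

import itertools

import dendropy
import numpy as np
import pytest

import floravision as fv
from floravision.categories import DistanceMatrix, euclidean_distances
from floravision.phylo import p_distance_matrix, tip_labels

from conftest import random_distance_matrix


def get_tree(newick, **kw):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True, **kw)


def brute_force_parsimony(tree, tip_states, alphabet):
    """Oracle: exhaustive enumeration of internal-node labelings.

    Returns (min changes, {clade: MPR set}) by minimising the number of
    edges whose endpoints differ, over every assignment of states to
    internal nodes.
    """
    internals = list(tree.preorder_internal_node_iter())
    leaves = list(tree.leaf_node_iter())
    best = None
    per_node_best: dict = {}
    for assignment in itertools.product(alphabet, repeat=len(internals)):
        state = {node: s for node, s in zip(internals, assignment)}
        state.update({leaf: tip_states[leaf.taxon.label] for leaf in leaves})
        cost = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None and state[node] != state[node.parent_node]
        )
        if best is None or cost < best:
            best = cost
            per_node_best = {n: {state[n]} for n in internals}
        elif cost == best:
            for n in internals:
                per_node_best[n].add(state[n])
    mpr = {
        frozenset(l.taxon.label for l in n.leaf_iter()): frozenset(per_node_best[n])
        for n in internals
    }
    return best, mpr


class TestNewickIO:
    def test_two_tip_tree(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,B:2);\n")
        tree = fv.read_newick(path)
        assert sorted(tip_labels(tree)) == ["A", "B"]
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_random_tree_roundtrip(self, tmp_path):
        tree = fv.simulate_yule_tree(20, 1.0, seed=3)
        path = tmp_path / "r.nwk"
        fv.write_newick(tree, path)
        back = fv.read_newick(path)
        d1 = fv.patristic_distances(tree)
        d2 = fv.patristic_distances(back)
        assert d1.labels == d2.labels
        assert np.allclose(d1.values, d2.values)

    def test_malformed_newick_rejected(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A,B),C;")
        with pytest.raises(Exception):
            fv.read_newick(path)


class TestZeroLengthTips:
    def test_duplicate_at_distance_zero(self):
        tree = get_tree("(A:1,B:1);")
        out = fv.add_zero_length_tips(tree, {"A": 1})
        d = fv.patristic_distances(out)
        i, j, k = (d.labels.index(x) for x in ("A", "A#2", "B"))
        assert d.values[i, j] == 0.0
        assert d.values[j, k] == pytest.approx(2.0)

    def test_count_zero_noop(self):
        tree = get_tree("(A:1,B:1);")
        out = fv.add_zero_length_tips(tree, {"A": 0})
        assert sorted(tip_labels(out)) == ["A", "B"]

    def test_two_duplicated_taxa_in_five_tip_tree(self):
        tree = fv.simulate_yule_tree(5, 1.0, seed=4)
        out = fv.add_zero_length_tips(tree, {"t1": 1, "t3": 1})
        assert len(tip_labels(out)) == 7

    def test_existing_distances_unchanged(self):
        tree = fv.simulate_yule_tree(6, 1.0, seed=5)
        before = fv.patristic_distances(tree)
        after = fv.patristic_distances(fv.add_zero_length_tips(tree, {"t2": 2}))
        sub = after.submatrix(before.labels)
        assert np.allclose(sub.values, before.values)

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            fv.add_zero_length_tips(get_tree("(A:1,B:1);"), {"Z": 1})


class TestPatristic:
    def test_cherry(self):
        d = fv.patristic_distances(get_tree("(A:1,B:2);"))
        assert d.values[d.labels.index("A"), d.labels.index("B")] == pytest.approx(3.0)

    def test_yule_tree_is_ultrametric(self):
        d = fv.patristic_distances(fv.simulate_yule_tree(6, 1.0, seed=6))
        v = d.values
        n = len(d.labels)
        for i, j, k in itertools.combinations(range(n), 3):
            sides = sorted([v[i, j], v[i, k], v[j, k]])
            assert sides[1] == pytest.approx(sides[2], rel=1e-9)


class TestMantel:
    def test_perfect_correlation_min_p(self):
        rng = np.random.default_rng(21)
        d1 = random_distance_matrix(rng, 6)
        d2 = DistanceMatrix(d1.labels, 2.0 * d1.values)
        res = fv.mantel_test(d1, d2, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 200.0)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(22)
        d1 = random_distance_matrix(rng, 5)
        d2 = random_distance_matrix(rng, 5, labels=list("vwxyz"))
        with pytest.raises(ValueError, match="labels"):
            fv.mantel_test(d1, d2)

    def test_matches_exhaustive_enumeration_n5(self):
        rng = np.random.default_rng(23)
        d1 = random_distance_matrix(rng, 5)
        d2 = random_distance_matrix(rng, 5)
        iu = np.triu_indices(5, 1)
        x = d1.values[iu]
        r_obs = np.corrcoef(x, d2.values[iu])[0, 1]
        rs = []
        for perm in itertools.permutations(range(5)):
            p = np.array(perm)
            rs.append(np.corrcoef(x, d2.values[np.ix_(p, p)][iu])[0, 1])
        p_exact = np.mean(np.array(rs) >= r_obs - 1e-12)
        res = fv.mantel_test(d1, d2, n_perm=10000, seed=1)
        assert abs(res.p - p_exact) <= 1.0 / 120.0

    def test_cross_check_against_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(24)
        d1 = random_distance_matrix(rng, 8)
        d2 = random_distance_matrix(rng, 8)
        ours = fv.mantel_test(d1, d2, n_perm=999, seed=2)
        theirs_r = skbio_mantel(
            SkbioDM(d1.values, ids=d1.labels),
            SkbioDM(d2.values, ids=d2.labels),
            method="pearson",
            permutations=0,
        )[0]
        assert ours.r == pytest.approx(float(theirs_r), abs=1e-12)


class TestMantelOverTrees:
    def test_identical_trees_shared_permutations_zero_sd(self):
        tree = fv.simulate_yule_tree(8, 1.0, seed=7)
        trees = [tree.clone(depth=1) for _ in range(10)]
        rng = np.random.default_rng(25)
        traits = random_distance_matrix(rng, 8, labels=sorted(tip_labels(tree)))
        summary = fv.mantel_over_trees(
            trees, traits, n_perm=99, seed=3, share_permutations=True
        )
        assert summary.sd_p == pytest.approx(0.0, abs=1e-12)
        assert summary.n_trees == 10

    def test_shuffled_traits_show_no_signal(self):
        rng = np.random.default_rng(26)
        tree = fv.simulate_yule_tree(20, 1.0, seed=8)
        traits = fv.synthetic_data.simulate_brownian_trait(tree, n_dims=3, seed=9)
        labels = sorted(traits)
        shuffled = rng.permutation(labels)
        vectors = np.array([traits[l] for l in shuffled])
        trait_d = euclidean_distances(vectors, labels=labels)
        trees = [tree.clone(depth=1) for _ in range(10)]
        summary = fv.mantel_over_trees(trees, trait_d, n_perm=199, seed=4)
        assert summary.mean_p > 0.05

    def test_missing_taxon_trees_skipped_with_count(self):
        tree = fv.simulate_yule_tree(8, 1.0, seed=10)
        small = fv.simulate_yule_tree(4, 1.0, seed=11)
        rng = np.random.default_rng(27)
        traits = random_distance_matrix(rng, 8, labels=sorted(tip_labels(tree)))
        summary = fv.mantel_over_trees([tree, small], traits, n_perm=99, seed=5)
        assert summary.n_trees == 1
        assert summary.n_skipped == 1


class TestFitchParsimony:
    def test_uniform_states_zero_length(self):
        tree = get_tree("((A:1,B:1):1,C:1);")
        res = fv.fitch_parsimony_asr(tree, {"A": "W", "B": "W", "C": "W"})
        assert res.parsimony_length == 0
        assert all(s == {"W"} for s in res.node_sets.values())

    def test_four_tip_two_changes(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        res = fv.fitch_parsimony_asr(tree, {"A": "G", "B": "W", "C": "G", "D": "W"})
        assert res.parsimony_length == 2

    def test_missing_tip_scored_as_full_alphabet(self):
        tree = get_tree("((A:1,B:1):1,C:1);")
        res = fv.fitch_parsimony_asr(tree, {"A": "W", "B": "W", "C": None}, alphabet=["W", "G"])
        assert res.parsimony_length == 0

    def test_state_outside_alphabet_rejected(self):
        tree = get_tree("(A:1,B:1);")
        with pytest.raises(ValueError, match="alphabet"):
            fv.fitch_parsimony_asr(tree, {"A": "W", "B": "Q"}, alphabet=["W", "G"])

    @pytest.mark.parametrize("n_tips,n_states", [(4, 2), (5, 3), (6, 4)])
    def test_matches_exhaustive_oracle(self, n_tips, n_states):
        alphabet = list("WGPR")[:n_states]
        rng = np.random.default_rng(n_tips * 10 + n_states)
        for rep in range(10):
            tree = fv.simulate_yule_tree(n_tips, 1.0, rng)
            tips = {f"t{i + 1}": alphabet[rng.integers(n_states)] for i in range(n_tips)}
            res = fv.fitch_parsimony_asr(tree, tips, alphabet=alphabet)
            oracle_len, oracle_mpr = brute_force_parsimony(tree, tips, alphabet)
            assert res.parsimony_length == oracle_len
            for clade, states in oracle_mpr.items():
                assert res.node_sets[clade] == states

    def test_three_independent_origins_of_green(self):
        """Three separated green clades among non-green relatives need at
        least three gains of green under unordered parsimony."""
        newick = (
            "(((g1:1,g2:1):1,(w1:1,w2:1):1):1,"
            "(((g3:1,g4:1):1,w3:1):1,((g5:1,w4:1):1,w5:1):1):1);"
        )
        tips = {f"g{i}": "G" for i in range(1, 6)}
        tips.update({f"w{i}": "W" for i in range(1, 6)})
        res = fv.fitch_parsimony_asr(get_tree(newick), tips)
        assert res.parsimony_length == 3
        assert res.root_set == {"W"}


class TestConsensus:
    def test_identical_trees_reproduce_topology(self):
        tree = fv.simulate_yule_tree(8, 1.0, seed=12)
        trees = [tree.clone(depth=1) for _ in range(5)]
        cons = fv.majority_consensus(trees, threshold=0.95)
        # every original clade appears in the consensus
        orig = {frozenset(l.taxon.label for l in n.leaf_iter()) for n in tree.preorder_internal_node_iter()}
        got = {frozenset(l.taxon.label for l in n.leaf_iter()) for n in cons.preorder_internal_node_iter()}
        assert orig <= got

    def test_minority_clade_collapsed_at_high_threshold(self):
        ns = dendropy.TaxonNamespace()
        trees = [
            get_tree("((A:1,B:1):1,(C:1,D:1):1);", taxon_namespace=ns),
            get_tree("((A:1,B:1):1,(C:1,D:1):1);", taxon_namespace=ns),
            get_tree("((A:1,C:1):1,(B:1,D:1):1);", taxon_namespace=ns),
        ]
        # {A,B}|{C,D} is a single unrooted split at frequency 2/3; it may
        # surface as either complementary clade on the consensus
        split = {frozenset({"A", "B"}), frozenset({"C", "D"})}

        def proper_clades(tree):
            return {
                frozenset(l.taxon.label for l in n.leaf_iter())
                for n in tree.preorder_internal_node_iter()
                if 1 < len(n.leaf_nodes()) < 4
            }

        assert not (proper_clades(fv.majority_consensus(trees, threshold=0.95)) & split)
        assert proper_clades(fv.majority_consensus(trees, threshold=0.5)) & split

    def test_inconsistent_tip_sets_rejected(self):
        ns = dendropy.TaxonNamespace()
        trees = [
            get_tree("(A:1,B:1);", taxon_namespace=ns),
            get_tree("(A:1,C:1);", taxon_namespace=ns),
        ]
        with pytest.raises(ValueError, match="tip sets"):
            fv.majority_consensus(trees)


class TestASROverTrees:
    def test_identical_trees_match_single_tree_mpr(self):
        tree = fv.simulate_yule_tree(8, 1.0, seed=13)
        tips, _, _ = fv.simulate_mk_trait(tree, ["a", "b", "c"], 0.5, seed=14)
        single = fv.fitch_parsimony_asr(tree, tips)
        trees = [tree.clone(depth=1) for _ in range(6)]
        over = fv.asr_over_trees(trees, tips, tree)
        for clade, freqs in over.frequencies.items():
            mpr = single.node_sets[clade]
            expect = {s: 1.0 / len(mpr) for s in sorted(mpr)}
            assert freqs == pytest.approx(expect)
            assert over.coverage[clade] == 1.0

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(30)
        tree = fv.simulate_yule_tree(10, 1.0, rng)
        tips, _, _ = fv.simulate_mk_trait(tree, ["a", "b"], 0.8, rng)
        trees = [fv.synthetic_data.jitter_branch_lengths(tree, 0.3, rng) for _ in range(8)]
        over = fv.asr_over_trees(trees, tips, tree)
        for clade, freqs in over.frequencies.items():
            if freqs:
                assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_root_state_recovered_at_low_rate(self):
        recovered = 0
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            tree = fv.simulate_yule_tree(20, 1.0, rng)
            tips, truth, _ = fv.simulate_mk_trait(tree, ["a", "b", "c"], 0.15, rng)
            all_taxa = frozenset(tip_labels(tree))
            trees = [fv.synthetic_data.jitter_branch_lengths(tree, 0.2, rng) for _ in range(5)]
            over = fv.asr_over_trees(trees, tips, tree)
            if over.root_frequencies:
                modal = max(over.root_frequencies, key=over.root_frequencies.get)
                recovered += modal == truth[all_taxa]
        assert recovered >= 8


def test_p_distance_pairwise_deletion():
    d = p_distance_matrix({"a": "ACGT-A", "b": "ACTTTA", "c": "ACGTNA"})
    i, j = d.labels.index("a"), d.labels.index("b")
    assert d.values[i, j] == pytest.approx(1.0 / 5.0)  # gap site excluded
    k = d.labels.index("c")
    assert d.values[i, k] == 0.0
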