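"""Distances, neighbor joining, bootstrap, consensus and clade analyses."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from rgakit.phylo import (
    Alignment,
    DistanceMatrix,
    assign_clades,
    bootstrap_trees,
    genus_specific_clades,
    majority_rule_consensus,
    neighbor_joining,
    protein_distance,
    transition_matrix,
    tree_splits,
)
from rgakit.synth import generate_alignment


def random_tree(rng, labels, lengths=(0.1, 1.0)):
    taxa = dendropy.TaxonNamespace(list(labels))
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        p = dendropy.Node()
        for k in (i, j):
            p.add_child(nodes[k])
            nodes[k].edge.length = float(rng.uniform(*lengths))
        nodes = [x for idx, x in enumerate(nodes) if idx not in (i, j)] + [p]
    t = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0])
    t.is_rooted = False
    return t


def path_distance_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
    return D


def rf_distance(newick_a, newick_b):
    taxa = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=taxa)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=taxa)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


class TestDistances:
    def test_identical_sequences_zero_under_both_models(self):
        aln = Alignment(["a", "b"], ["MKVLEQ" * 20, "MKVLEQ" * 20])
        for model in ("kimura_corrected", "dayhoff_ml"):
            dm = protein_distance(aln, model=model)
            assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-5)

    def test_kimura_closed_form(self):
        # 10% mismatches: d = -ln(1 - 0.1 - 0.002) = 0.10754
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        dm = protein_distance(Alignment(["a", "b"], [a, b]), model="kimura_corrected")
        assert dm.values[0, 1] == pytest.approx(-math.log(1 - 0.1 - 0.002), abs=1e-9)
        assert dm.values[0, 1] == pytest.approx(0.1076, abs=1e-4)

    def test_gapped_columns_skipped_pairwise(self):
        aln = Alignment(["a", "b"], ["MK-LE", "MKVLE"])
        dm = protein_distance(aln, model="kimura_corrected")
        assert dm.values[0, 1] == 0.0

    def test_all_gap_pair_rejected(self):
        aln = Alignment(["a", "b", "c"], ["MK--", "--VL", "MKVL"])
        with pytest.raises(ValueError, match="'a'"):
            protein_distance(aln, model="kimura_corrected")

    def test_saturated_pair_flagged_at_ceiling(self):
        aln = Alignment(["a", "b"], ["A" * 50, "C" * 50])
        dm = protein_distance(aln, model="kimura_corrected", ceiling=8.0)
        assert dm.values[0, 1] == 8.0
        assert ("a", "b") in dm.saturated

    def test_dayhoff_ml_recovers_simulated_depth(self):
        """Pairs evolved at 0.5 substitutions/site are estimated at 0.5 +/- 0.1."""
        from rgakit.phylo import AMINO_ACIDS, dayhoff_rate_matrix

        rng = np.random.default_rng(7)
        _, f = dayhoff_rate_matrix()
        P = transition_matrix(0.5)
        estimates = []
        for _ in range(20):
            anc = rng.choice(20, size=400, p=f)
            der = np.array([rng.choice(20, p=P[s] / P[s].sum()) for s in anc])
            aln = Alignment(
                ["anc", "der"],
                ["".join(AMINO_ACIDS[i] for i in anc), "".join(AMINO_ACIDS[i] for i in der)],
            )
            estimates.append(protein_distance(aln, model="dayhoff_ml").values[0, 1])
        assert abs(np.mean(estimates) - 0.5) < 0.1


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(1)
        labels = [f"L{k}" for k in range(8)]
        for _ in range(30):
            true = random_tree(rng, labels)
            D = path_distance_matrix(true, labels)
            est = neighbor_joining(DistanceMatrix(labels, D))
            D2 = path_distance_matrix(est, labels)
            assert np.abs(D - D2).max() < 1e-9
            assert rf_distance(true.as_string(schema="newick"),
                               est.as_string(schema="newick")) == 0

    def test_label_order_invariance(self):
        rng = np.random.default_rng(2)
        labels = [f"L{k}" for k in range(7)]
        true = random_tree(rng, labels)
        D = path_distance_matrix(true, labels)
        t1 = neighbor_joining(DistanceMatrix(labels, D))
        perm = list(rng.permutation(len(labels)))
        labels_p = [labels[i] for i in perm]
        Dp = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(labels_p, Dp))
        assert rf_distance(t1.as_string(schema="newick"),
                           t2.as_string(schema="newick")) == 0

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 6
            labels = [f"x{k}" for k in range(n)]
            M = rng.uniform(0.1, 2.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            for edge in tree.edges():
                if edge.length is not None:
                    assert edge.length >= 0


class TestBootstrap:
    def test_identity_resample_equals_point_estimate(self, monkeypatch):
        aln, _ = generate_alignment(6, 120, 0.2, seed=4)
        monkeypatch.setattr(Alignment, "resample_columns", lambda self, rng: self)
        trees, _ = bootstrap_trees(aln, n_reps=1, seed=0)
        point = neighbor_joining(protein_distance(aln, model="kimura_corrected"))
        assert rf_distance(trees[0].as_string(schema="newick"),
                           point.as_string(schema="newick")) == 0

    def test_same_seed_identical_replicates(self):
        aln, _ = generate_alignment(6, 80, 0.3, seed=5)
        a, _ = bootstrap_trees(aln, n_reps=10, seed=42)
        b, _ = bootstrap_trees(aln, n_reps=10, seed=42)
        assert [t.as_string(schema="newick") for t in a] == \
               [t.as_string(schema="newick") for t in b]

    def test_strong_signal_split_in_most_replicates(self):
        # one split (t1,t2 | t3,t4) supported by many identical columns
        rows = ["A" * 40 + "C" * 10, "A" * 40 + "C" * 10,
                "D" * 40 + "C" * 10, "D" * 40 + "W" * 10]
        aln = Alignment(["t1", "t2", "t3", "t4"], rows)
        trees, _ = bootstrap_trees(aln, n_reps=200, seed=0)
        hits = sum(1 for t in trees if frozenset({"t3", "t4"}) in tree_splits(t)
                   or frozenset({"t1", "t2"}) in tree_splits(t))
        assert hits / len(trees) >= 0.95


class TestConsensus:
    def test_identical_trees_full_support(self):
        rng = np.random.default_rng(6)
        t = random_tree(rng, [f"L{k}" for k in range(6)])
        newick = t.as_string(schema="newick")
        trees = [dendropy.Tree.get(data=newick, schema="newick") for _ in range(10)]
        cons = majority_rule_consensus(trees)
        assert tree_splits(cons) == tree_splits(trees[0])
        supports = [int(n.label) for n in cons.preorder_node_iter()
                    if not n.is_leaf() and n.label is not None]
        assert supports and all(s == 100 for s in supports)

    def test_two_thirds_split_kept_with_support_67(self):
        t_ab = "((A:1,B:1):1,(C:1,(D:1,E:1):1):1);"
        t_ac = "((A:1,C:1):1,(B:1,(D:1,E:1):1):1);"
        trees = [dendropy.Tree.get(data=s, schema="newick")
                 for s in (t_ab, t_ab, t_ac)]
        cons = majority_rule_consensus(trees)
        supports = {
            frozenset(l.taxon.label for l in n.leaf_iter()): int(n.label)
            for n in cons.preorder_node_iter()
            if not n.is_leaf() and n.label is not None
        }
        # the A,B | C,D,E split is carried by the (C,D,E) node
        assert supports[frozenset({"C", "D", "E"})] == 67
        assert supports[frozenset({"D", "E"})] == 100

    def test_incompatible_half_splits_both_dropped(self):
        t1 = "((A:1,B:1):1,(C:1,D:1):1);"
        t2 = "((A:1,C:1):1,(B:1,D:1):1);"
        trees = [dendropy.Tree.get(data=s, schema="newick") for s in (t1, t2)]
        cons = majority_rule_consensus(trees)
        assert tree_splits(cons) == set()  # star tree

    def test_supports_are_multiples_of_grid(self):
        aln, _ = generate_alignment(6, 60, 0.4, seed=8)
        trees, _ = bootstrap_trees(aln, n_reps=20, seed=1)
        cons = majority_rule_consensus(trees)
        for node in cons.preorder_node_iter():
            if not node.is_leaf() and node.label is not None:
                assert int(node.label) > 50

    def test_differing_leaf_sets_rejected(self):
        t1 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        t2 = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,E:1):1);", schema="newick")
        with pytest.raises(ValueError, match="leaf"):
            majority_rule_consensus([t1, t2])


class TestGenusClades:
    def test_two_cherries_two_clades(self):
        tree = dendropy.Tree.get(data="((a1:1,a2:1):1,(b1:1,b2:1):1);", schema="newick")
        clades, mixed = genus_specific_clades(
            tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )
        assert clades == [("A", ("a1", "a2")), ("B", ("b1", "b2"))]
        assert frozenset({"A", "B"}) in mixed

    def test_maximality_reports_only_largest(self):
        tree = dendropy.Tree.get(
            data="(((a1:1,a2:1):1,a3:1):1,(b1:1,b2:1):1);", schema="newick"
        )
        clades, _ = genus_specific_clades(
            tree, {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        )
        assert ("A", ("a1", "a2", "a3")) in clades
        assert ("A", ("a1", "a2")) not in clades

    def test_min_size_filters(self):
        tree = dendropy.Tree.get(data="((a1:1,b1:1):1,(b2:1,b3:1):1);", schema="newick")
        clades, _ = genus_specific_clades(
            tree, {"a1": "A", "b1": "B", "b2": "B", "b3": "B"}, min_size=2
        )
        assert clades == [("B", ("b2", "b3"))]

    def test_unmapped_leaf_rejected(self):
        tree = dendropy.Tree.get(data="((a1:1,a2:1):1,b1:1);", schema="newick")
        with pytest.raises(ValueError, match="b1"):
            genus_specific_clades(tree, {"a1": "A", "a2": "A"})

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 12))
            labels = [f"x{k}" for k in range(n)]
            groups = {l: str(rng.choice(["A", "B", "C"])) for l in labels}
            tree = random_tree(rng, labels)
            clades, _ = genus_specific_clades(tree, groups, min_size=2)
            # brute force: scan every internal node independently
            want = []
            for node in tree.preorder_node_iter():
                if node.is_leaf():
                    continue
                leaves = sorted(l.taxon.label for l in node.leaf_iter())
                gs = {groups[l] for l in leaves}
                if len(gs) != 1 or len(leaves) < 2:
                    continue
                parent = node.parent_node
                if parent is not None:
                    pgs = {groups[l.taxon.label] for l in parent.leaf_iter()}
                    if len(pgs) == 1:
                        continue
                want.append((gs.pop(), tuple(leaves)))
            assert sorted(clades) == sorted(want)


class TestAssignClades:
    def test_subtree_definitions_monophyletic(self):
        tree = dendropy.Tree.get(
            data="(((a1:1,a2:1):1,a3:1):1,(b1:1,b2:1):1);", schema="newick"
        )
        mapping, mono = assign_clades(
            tree, {"TN1": {"a1", "a2", "a3"}, "CN1": {"b1", "b2"}}
        )
        assert mono == {"TN1": True, "CN1": True}
        assert mapping["a2"] == "TN1"

    def test_split_cherry_flagged(self):
        tree = dendropy.Tree.get(data="((a1:1,a2:1):1,(b1:1,b2:1):1);", schema="newick")
        _, mono = assign_clades(tree, {"bad": {"a1", "b1"}})
        assert mono == {"bad": False}

    def test_overlapping_definitions_rejected(self):
        tree = dendropy.Tree.get(data="((a1:1,a2:1):1,b1:1);", schema="newick")
        with pytest.raises(ValueError, match="a1"):
            assign_clades(tree, {"X": {"a1"}, "Y": {"a1", "a2"}})

    def test_planted_clade_structure_recovered(self):
        # eleven planted clades on one simulated tree, all monophyletic
        rng = np.random.default_rng(13)
        defs = {}
        subtrees = []
        k = 0
        for c in range(11):
            size = int(rng.integers(2, 5))
            leaves = [f"m{k + i}" for i in range(size)]
            k += size
            defs[f"clade{c}"] = set(leaves)
            inner = ",".join(f"{l}:0.1" for l in leaves)
            subtrees.append(f"({inner}):1.0")
        tree = dendropy.Tree.get(data="(" + ",".join(subtrees) + ");", schema="newick")
        _, mono = assign_clades(tree, defs)
        assert all(mono.values())
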