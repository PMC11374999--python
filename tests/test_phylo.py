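"""Supermatrix assembly, midpoint rooting and RF distance, each checked
against brute-force oracles (and dendropy as an independent library route).
"""

import itertools

import dendropy
import numpy as np
import pytest

import digitalmicrobe as dm
from digitalmicrobe.errors import ValidationError
from digitalmicrobe.phylo import (
    AlignmentBlock,
    leaf_order,
    midpoint_root,
    read_newick,
    root_to_leaf_depths,
    topology_distance,
    write_newick,
)


def random_newick(rng, n_leaves):
    """Random binary tree with uniform(0.1, 2.0) branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    subtrees = {name: f"{name}:{rng.uniform(0.1, 2.0):.3f}" for name in nodes}
    alive = list(nodes)
    while len(alive) > 2:
        a, b = rng.choice(len(alive), size=2, replace=False)
        na, nb = alive[int(a)], alive[int(b)]
        merged = f"({subtrees[na]},{subtrees[nb]}):{rng.uniform(0.1, 2.0):.3f}"
        key = f"{na}+{nb}"
        subtrees[key] = merged
        alive = [x for x in alive if x not in (na, nb)] + [key]
    a, b = alive
    return f"({subtrees[a]},{subtrees[b]});"


def brute_force_pairwise_max(newick):
    """Longest leaf-to-leaf distance by exhaustive dendropy PDM lookup."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    best = 0.0
    for t1, t2 in itertools.combinations(taxa, 2):
        best = max(best, pdm.distance(t1, t2))
    return best


def brute_force_bipartitions(newick):
    """Non-trivial splits by explicit leaf-set enumeration per edge."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(all_leaves - side if anchor in side else side)
    return splits


class TestSupermatrix:
    def test_widths_concatenate(self):
        blocks = [
            AlignmentBlock("b1", [("g1", "A" * 10), ("g2", "C" * 10), ("g3", "G" * 10)]),
            AlignmentBlock("b2", [("g1", "M" * 15), ("g2", "K" * 15), ("g3", "R" * 15)]),
        ]
        matrix, parts = dm.concatenate_scg_alignments(blocks, ["g1", "g2", "g3"])
        assert all(len(seq) == 25 for seq in matrix.values())
        assert parts["start"].tolist() == [1, 11]
        assert parts["end"].tolist() == [10, 25]

    def test_missing_genome_gap_filled(self):
        blocks = [
            AlignmentBlock("b1", [("g1", "AAAA"), ("g2", "CCCC")]),
            AlignmentBlock("b2", [("g1", "MMM")]),
        ]
        matrix, _ = dm.concatenate_scg_alignments(blocks, ["g1", "g2"])
        assert matrix["g2"] == "CCCC" + "---"

    def test_double_row_rejected_not_single_copy(self):
        blocks = [AlignmentBlock("b1", [("g1", "AAAA"), ("g1", "CCCC")])]
        with pytest.raises(ValidationError, match="single-copy"):
            dm.concatenate_scg_alignments(blocks, ["g1"])

    def test_ragged_block_rejected(self):
        blocks = [AlignmentBlock("b1", [("g1", "AAAA"), ("g2", "CC")])]
        with pytest.raises(ValidationError, match="unequal"):
            dm.concatenate_scg_alignments(blocks, ["g1", "g2"])


class TestNewickIO:
    def test_read_write_read_stable(self):
        nwk = "((A:1.0,B:3.0):1.0,C:6.0);"
        once = write_newick(read_newick(nwk))
        twice = write_newick(read_newick(once))
        assert once == twice

    def test_leaf_order(self):
        assert leaf_order("((A:1,B:1):1,C:1);") == ["A", "B", "C"]


class TestMidpointRoot:
    def test_worked_three_leaf_tree(self):
        rooted = midpoint_root(read_newick("((A:1,B:3):1,C:6);"))
        depths = root_to_leaf_depths(rooted)
        # longest path B-C has length 10; root 5 from each; A at 3
        assert depths["B"] == pytest.approx(5.0)
        assert depths["C"] == pytest.approx(5.0)
        assert depths["A"] == pytest.approx(3.0)

    def test_two_leaf_tree_split_evenly(self):
        rooted = midpoint_root(read_newick("(A:2,B:4);"))
        depths = root_to_leaf_depths(rooted)
        assert depths["A"] == pytest.approx(3.0)
        assert depths["B"] == pytest.approx(3.0)

    def test_idempotent_on_midpoint_tree(self):
        once = midpoint_root(read_newick("((A:1,B:3):1,C:6);"))
        twice = midpoint_root(read_newick(write_newick(once)))
        assert root_to_leaf_depths(twice) == pytest.approx(root_to_leaf_depths(once))

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValidationError, match="branch length"):
            midpoint_root(read_newick("((A,B),C);"))

    @pytest.mark.parametrize("seed", range(25))
    def test_minimax_property_on_random_trees(self, seed):
        """Max root-to-leaf depth equals half the brute-force tree diameter,
        and the deepest leaves are equidistant."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        nwk = random_newick(rng, n)
        rooted = midpoint_root(read_newick(nwk))
        depths = root_to_leaf_depths(rooted)
        diameter = brute_force_pairwise_max(nwk)
        assert max(depths.values()) == pytest.approx(diameter / 2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_dendropy_midpoint_depth(self, seed):
        rng = np.random.default_rng(100 + seed)
        nwk = random_newick(rng, 6)
        ours = max(root_to_leaf_depths(midpoint_root(read_newick(nwk))).values())
        dtree = dendropy.Tree.get(data=nwk, schema="newick")
        dtree.reroot_at_midpoint(update_bipartitions=False)
        theirs = max(
            leaf.distance_from_root() for leaf in dtree.leaf_node_iter()
        )
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1);"
        assert topology_distance(nwk, nwk) == (0, 0.0)

    def test_four_leaf_swap_is_maximal(self):
        rf, norm = topology_distance("((A,B),(C,D));", "((A,C),(B,D));")
        assert rf == 2
        assert norm == pytest.approx(1.0)

    def test_star_vs_resolved(self):
        star = "(A,B,C,D,E);"
        resolved = "((A,B),(C,(D,E)));"
        rf, _ = topology_distance(star, resolved)
        assert rf == len(brute_force_bipartitions(resolved))

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(ValidationError, match="leaf sets differ"):
            topology_distance("((A,B),C);", "((A,B),D);")

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_bipartition_enumeration_and_dendropy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        nwk1 = random_newick(rng, n)
        nwk2 = random_newick(rng, n)
        rf, _ = topology_distance(nwk1, nwk2)
        oracle = len(brute_force_bipartitions(nwk1) ^ brute_force_bipartitions(nwk2))
        assert rf == oracle
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert rf == dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestAttachTree:
    def test_attach_and_idempotent_reattach(self, toy_pkg):
        nwk = "((A:1,B:1):1,C:1);"
        leaves = dm.attach_tree(toy_pkg, nwk, role="core_phylogeny")
        version = toy_pkg.manifest.version
        assert leaves == ["A", "B", "C"]
        assert toy_pkg.has_layer("tree:core_phylogeny")
        # re-attaching the identical tree does not bump the version
        dm.attach_tree(toy_pkg, nwk, role="core_phylogeny")
        assert toy_pkg.manifest.version == version

    def test_stray_leaf_rejected_for_pangenome(self):
        from digitalmicrobe.synthetic import simulate_protein_families

        pkg = dm.create_package("pan", "pangenome")
        pkg.pangenome = dm.build_pangenome(
            simulate_protein_families(1, n_genomes=3, n_shared=2, n_unique=0)
        )
        with pytest.raises(ValidationError, match="X"):
            dm.attach_tree(pkg, "((G01:1,X:1):1,(G02:1,G03:1):1);")
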