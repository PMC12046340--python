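import itertools

import numpy as np
import pytest

from barcodepop.distmat import DistanceMatrix, pairwise_matrix
from barcodepop.njtree import (
    Node,
    PhyloTree,
    bootstrap,
    is_monophyletic,
    nj_build,
    root_on,
)

from conftest import make_set


def dm(labels, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(labels=list(labels), d=d,
                          saturated=np.zeros_like(d, dtype=bool))


def random_tree(names, rng):
    """Random binary tree with exponential branch lengths."""
    nodes = [Node(name=n, length=float(rng.exponential(0.1)) + 0.01)
             for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = Node(children=[a, b], length=float(rng.exponential(0.1)) + 0.01)
        nodes.append(parent)
    return PhyloTree(root=Node(children=nodes))


def tree_metric(tree):
    leaves, d = tree.path_lengths()
    return leaves, d


class TestNJ:
    def test_three_taxa_three_point_formulas(self):
        d = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = nj_build(dm("abc", d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_four_taxon_additive_recovery_vs_least_squares(self, rng):
        """NJ beats brute-force least-squares over all 3 unrooted topologies."""
        for _ in range(20):
            # additive matrix from a known quartet ((a,b),(c,d))
            ea, eb, ec, ed, em = rng.uniform(0.05, 0.5, size=5)
            d = np.array(
                [
                    [0, ea + eb, ea + em + ec, ea + em + ed],
                    [ea + eb, 0, eb + em + ec, eb + em + ed],
                    [ea + em + ec, eb + em + ec, 0, ec + ed],
                    [ea + em + ed, eb + em + ed, ec + ed, 0],
                ]
            )
            tree = nj_build(dm("abcd", d))
            leaves, rec = tree_metric(tree)
            order = [leaves.index(x) for x in "abcd"]
            assert np.allclose(rec[np.ix_(order, order)], d, atol=1e-9)
            # oracle: the quartet split with the smallest LS residual
            best = min(
                [("ab|cd", (d[0, 1] + d[2, 3])), ("ac|bd", (d[0, 2] + d[1, 3])),
                 ("ad|bc", (d[0, 3] + d[1, 2]))],
                key=lambda kv: kv[1],
            )[0]
            assert best == "ab|cd"  # four-point condition on the additive input
            assert frozenset("ab") in tree.split_set() or frozenset(
                "cd") in tree.split_set()

    def test_consistency_on_random_additive_matrices(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 11))
            names = [f"t{i}" for i in range(n)]
            true = random_tree(names, rng)
            leaves, d = tree_metric(true)
            rec = nj_build(dm(leaves, d))
            assert rec.split_set() == true.split_set()
            rl, rd = tree_metric(rec)
            order = [rl.index(x) for x in leaves]
            assert np.allclose(rd[np.ix_(order, order)], d, atol=1e-9)

    def test_agrees_with_skbio_on_additive_input(self, rng):
        skbio = pytest.importorskip("skbio")
        names = [f"t{i}" for i in range(8)]
        true = random_tree(names, rng)
        leaves, d = tree_metric(true)
        ours = nj_build(dm(leaves, d))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=leaves))
        sk_splits = set()
        all_leaves = frozenset(leaves)
        ref = min(all_leaves)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(all_leaves) - 2:
                side = frozenset(all_leaves - side) if ref in side else side
                sk_splits.add(side)
        assert ours.split_set() == sk_splits

    def test_nan_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        m = DistanceMatrix(labels=["a", "b", "c"], d=d,
                           saturated=np.zeros((3, 3), dtype=bool))
        with pytest.raises(ValueError, match="complete deletion"):
            nj_build(m)


class TestBootstrap:
    def clusters(self):
        # two well-separated clusters: within distance 0, between ~0.2
        left = "A" * 50
        right = "A" * 25 + "G" * 13 + "T" * 12
        return make_set(
            [("a1", "X", left), ("a2", "X", left),
             ("b1", "Y", right), ("b2", "Y", right)]
        )

    def test_clean_split_gets_full_support(self):
        tree = bootstrap(self.clusters(), replicates=50, seed=1)
        supports = [n.support for n in tree.splits().values()]
        assert supports == [100.0]

    def test_deterministic_given_seed(self, rng):
        from conftest import related_seqs

        a = make_set(
            [(f"s{i}", "X", s) for i, s in
             enumerate(related_seqs(rng, 6, 100, divergence=0.12))]
        )
        t1 = bootstrap(a, replicates=30, seed=7)
        t2 = bootstrap(a, replicates=30, seed=7)
        s1 = {k: v.support for k, v in t1.splits().items()}
        s2 = {k: v.support for k, v in t2.splits().items()}
        assert s1 == s2

    def test_supports_in_range_and_only_on_point_tree_splits(self, rng):
        from conftest import related_seqs

        a = make_set(
            [(f"s{i}", "X", s) for i, s in
             enumerate(related_seqs(rng, 7, 80, divergence=0.12))]
        )
        tree = bootstrap(a, replicates=20, seed=3)
        for node in tree.splits().values():
            assert 0.0 <= node.support <= 100.0


class TestRootingAndMonophyly:
    def test_root_on_single_leaf(self, rng):
        true = random_tree(["a", "b", "c", "d"], rng)
        rooted = root_on(true, "a")
        assert len(rooted.root.children) == 2
        sides = [c.leaf_names() for c in rooted.root.children]
        assert frozenset(["a"]) in sides
        assert rooted.total_branch_length() == pytest.approx(
            true.total_branch_length()
        )

    def test_rooting_preserves_split_set(self, rng):
        true = random_tree([f"t{i}" for i in range(7)], rng)
        rooted = root_on(true, "t3")
        assert rooted.split_set() == true.split_set()

    def test_non_monophyletic_outgroup_rejected(self):
        # quartet ((a,b),(c,d)): {a, c} is not a split
        d = [[0, 0.2, 1, 1], [0.2, 0, 1, 1], [1, 1, 0, 0.2], [1, 1, 0.2, 0]]
        tree = nj_build(dm("abcd", d))
        with pytest.raises(ValueError, match="not monophyletic"):
            root_on(tree, ["a", "c"])

    def test_singleton_always_monophyletic(self, rng):
        tree = random_tree([f"t{i}" for i in range(6)], rng)
        ok, _ = is_monophyletic(tree, ["t2"])
        assert ok

    def test_agrees_with_exhaustive_bipartition_scan(self, rng):
        for _ in range(10):
            names = [f"t{i}" for i in range(7)]
            tree = random_tree(names, rng)
            all_splits = set(tree.splits(include_trivial=True).keys())
            universe = frozenset(names)
            ref = min(universe)
            for size in range(1, 6):
                for subset in itertools.combinations(names, size):
                    subset = frozenset(subset)
                    canon = (
                        frozenset(universe - subset) if ref in subset else subset
                    )
                    expected = (
                        size == 1
                        or size == len(names)
                        or canon in all_splits
                    )
                    got, _ = is_monophyletic(tree, subset)
                    assert got == expected

    def test_unknown_tip_rejected(self, rng):
        tree = random_tree(["a", "b", "c", "d"], rng)
        with pytest.raises(KeyError):
            is_monophyletic(tree, ["zz"])
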