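"""Neighbor-joining trees, bootstrap supports, rooting and monophyly.

Saitou & Nei's neighbor-joining agglomerates a distance matrix with the
standard Q-criterion and is consistent on additive matrices: when the input
equals the path-length metric of some tree, that tree (topology and branch
lengths) is recovered exactly.  Tie-breaking during Q-minimization picks
the lowest (i, j) index pair so runs are bit-reproducible.  Negative branch
lengths (possible on non-additive input) are clamped to zero with the
excess transferred to the adjacent edge, and logged.

Bootstrap resamples alignment columns with replacement; support for each
internal bipartition of the point-estimate tree is the percentage of
replicate trees containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distmat import DistanceMatrix, pairwise_matrix
from .seqio import AlignedSet

__all__ = [
    "Node",
    "PhyloTree",
    "nj_build",
    "bootstrap",
    "root_on",
    "is_monophyletic",
]

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class Node:
    """Tree node; ``length`` is the edge to the parent (root: 0)."""

    name: str | None = None  # leaf seq_id; None for internal nodes
    children: list["Node"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None  # bootstrap %, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class PhyloTree:
    """A phylogeny over seq_ids, possibly with bootstrap supports.

    The unrooted representation has one trifurcation at the arbitrary
    ``root``; after :func:`root_on` the root is binary.  Supports live on
    internal edges only.
    """

    root: Node

    @property
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def _canon(self, side: frozenset[str]) -> frozenset[str]:
        ref = min(self.leaf_names)
        return frozenset(self.leaf_names - side) if ref in side else side

    def splits(self, include_trivial: bool = False) -> dict[frozenset[str], Node]:
        """Canonical bipartitions (side not containing the reference leaf).

        Maps each split to the child node whose subtree realizes it; the
        node carries the edge's length and support.  Trivial splits
        (single leaves) are excluded unless requested.
        """
        all_leaves = self.leaf_names
        out: dict[frozenset[str], Node] = {}
        stack = list(self.root.children)
        while stack:
            n = stack.pop()
            stack.extend(n.children)
            side = n.leaf_names()
            if not include_trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out[self._canon(side)] = n
        return out

    def split_set(self) -> frozenset[frozenset[str]]:
        """Internal bipartitions only — the unrooted topology signature."""
        return frozenset(self.splits().keys())

    def total_branch_length(self) -> float:
        total = 0.0
        stack = list(self.root.children)
        while stack:
            n = stack.pop()
            total += n.length
            stack.extend(n.children)
        return total

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length metric (for additivity checks)."""
        leaves = sorted(self.leaf_names)
        idx = {name: i for i, name in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def below(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            merged: dict[str, float] = {}
            parts = []
            for c in node.children:
                sub = {k: v + c.length for k, v in below(c).items()}
                parts.append(sub)
            for a_i in range(len(parts)):
                for b_i in range(a_i + 1, len(parts)):
                    for la, da in parts[a_i].items():
                        for lb, db in parts[b_i].items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
            for sub in parts:
                merged.update(sub)
            return merged

        below(self.root)
        return leaves, d

    def to_newick(self, digits: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})"
                if node.support is not None:
                    label += f"{int(round(node.support))}"
            return f"{label}:{node.length:.{digits}g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_build(m: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix.

    Requires >= 3 labels and a finite matrix; NaN entries (saturated K2P
    pairs) are an error — recompute the matrix under complete deletion.
    """
    labels = list(m.labels)
    if len(labels) < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in distance matrix")
    if np.isnan(m.d).any():
        raise ValueError(
            "distance matrix contains NaN (saturated pairs); "
            "recompute with complete deletion or drop the offending sequences"
        )

    nodes: list[Node] = [Node(name=l) for l in labels]
    D = m.d.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        # Q-criterion; flat argmin over the upper triangle visits pairs in
        # lexicographic order, so ties break on the lowest (i, j)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        Q[np.tril_indices(n)] = np.inf
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = Node(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final 3-star with the three-point formulas
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, l in zip((a, b, c), (la, lb, lc)):
        if l < 0:
            logger.debug("clamped negative terminal branch %.3g to 0", l)
            l = 0.0
        node.length = l
    return PhyloTree(root=Node(children=[a, b, c]))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the excess to its pair."""
    if li < 0:
        logger.debug("clamped negative branch %.3g to 0 (excess transferred)", li)
        lj += li
        li = 0.0
    if lj < 0:
        logger.debug("clamped negative branch %.3g to 0 (excess transferred)", lj)
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


def bootstrap(
    a: AlignedSet,
    replicates: int = 1000,
    seed: int = 0,
    deletion: str = "pairwise",
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement per replicate; support
    is the percentage of usable replicates whose NJ tree contains the
    bipartition.  Replicates whose resampled matrix has a saturated (NaN)
    pair are skipped and logged.  Deterministic given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .distmat import encode, matrix_from_codes

    tree = nj_build(pairwise_matrix(a, deletion=deletion))
    target = tree.splits()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    codes = encode(a.sequences())
    if deletion == "complete":
        codes = codes[:, np.all(codes < 4, axis=0)]
    L = codes.shape[1]
    used = 0
    skipped = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        try:
            m = matrix_from_codes(codes[:, cols], a.ids)
            rep = nj_build(m)
        except ValueError:
            skipped += 1
            continue
        used += 1
        rep_splits = rep.split_set()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    if skipped:
        logger.warning("skipped %d bootstrap replicates (saturation)", skipped)
    if used == 0:
        raise ValueError("all bootstrap replicates were skipped")
    for split, node in target.items():
        node.support = 100.0 * counts[split] / used
    return tree


def _adjacency(tree: PhyloTree) -> dict[Node, list[tuple[Node, float, float | None]]]:
    adj: dict[Node, list[tuple[Node, float, float | None]]] = {tree.root: []}
    stack = [tree.root]
    while stack:
        n = stack.pop()
        for c in n.children:
            adj.setdefault(c, [])
            adj[n].append((c, c.length, c.support))
            adj[c].append((n, c.length, c.support))
            stack.append(c)
    return adj


def root_on(tree: PhyloTree, outgroup: str | Iterable[str]) -> PhyloTree:
    """Root the tree on an outgroup leaf or clade.

    The root is inserted at the midpoint of the outgroup's pendant edge
    (single leaf) or the stem edge of the outgroup clade.  The outgroup
    must form a split on the unrooted tree, else an error is raised.
    Total branch length is preserved.
    """
    names = tree.leaf_names
    og = frozenset([outgroup]) if isinstance(outgroup, str) else frozenset(outgroup)
    unknown = og - names
    if unknown:
        raise KeyError(f"outgroup tip(s) not in tree: {sorted(unknown)}")
    if og == names:
        raise ValueError("outgroup cannot be the whole tree")

    adj = _adjacency(tree)

    # find the edge whose removal isolates exactly the outgroup
    def side_leaves(frm: Node, to: Node) -> frozenset[str]:
        out = set()
        stack = [(frm, to)]
        while stack:
            prev, cur = stack.pop()
            if cur.is_leaf:
                out.add(cur.name)
            for nxt, _, _ in adj[cur]:
                if nxt is not prev:
                    stack.append((cur, nxt))
        return frozenset(out)

    edge = None
    for u in adj:
        for v, length, support in adj[u]:
            if id(u) < id(v):
                continue
            if side_leaves(u, v) == og or side_leaves(v, u) == og:
                og_end = v if side_leaves(u, v) == og else u
                other = u if og_end is v else v
                edge = (og_end, other, length, support)
                break
        if edge:
            break
    if edge is None:
        raise ValueError("outgroup is not monophyletic on the unrooted tree")

    og_end, other, length, support = edge

    def rebuild(node: Node, parent: Node | None) -> Node:
        new = Node(name=node.name)
        for nxt, l, s in adj[node]:
            if nxt is parent:
                continue
            child = rebuild(nxt, node)
            child.length = l
            child.support = s
            new.children.append(child)
        return new

    og_side = rebuild(og_end, other)
    other_side = rebuild(other, og_end)
    og_side.length = other_side.length = length / 2.0
    og_side.support = other_side.support = support
    return PhyloTree(root=Node(children=[og_side, other_side]))


def is_monophyletic(
    tree: PhyloTree, tips: Iterable[str]
) -> tuple[bool, Node | None]:
    """Does ``tips`` form a clade under the unrooted-bipartition convention?

    Returns the verdict plus the supporting edge's node (carrying length
    and bootstrap support) when one exists.  Singletons are always
    monophyletic (their pendant edge isolates them).
    """
    subset = frozenset(tips)
    if not subset:
        raise ValueError("empty tip subset")
    names = tree.leaf_names
    unknown = subset - names
    if unknown:
        raise KeyError(f"unknown tip id(s): {sorted(unknown)}")
    if len(subset) == 1 or subset == names:
        return True, None
    splits = tree.splits(include_trivial=True)
    node = splits.get(tree._canon(subset))
    return (node is not None), node
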