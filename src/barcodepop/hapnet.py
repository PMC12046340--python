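"""Haplotype collapsing and minimum spanning networks.

Sequences are first restricted to columns where every record carries an
unambiguous base (the convention of network software for barcode data), so
"mutational steps" count only universally resolved sites.  Identical
filtered sequences collapse into haplotypes; the network is the minimum
spanning network (MSN, epsilon = 0): the union of all minimum spanning
trees of the complete Hamming graph over haplotypes.  An edge belongs to
the MSN iff its endpoints are not already connected using strictly
cheaper edges (the cycle property), which the Kruskal-style pass below
applies one weight class at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .seqio import AlignedSet, SequenceRecord

__all__ = [
    "Haplotype",
    "filter_columns",
    "collapse",
    "hamming",
    "build_msn",
    "group_separation",
]

_ACGT = frozenset("ACGT")


@dataclass
class Haplotype:
    """A unique (filtered) sequence with its carriers.

    ``frequency`` equals the number of member seq_ids; ``groups`` counts
    members per population label (None-labelled members keyed "").
    """

    hap_id: str
    sequence: str
    members: list[str]
    groups: dict[str, int] = field(default_factory=dict)

    @property
    def frequency(self) -> int:
        return len(self.members)


def filter_columns(a: AlignedSet) -> tuple[AlignedSet, list[int]]:
    """Drop columns with any gap/ambiguity; return the kept-column map.

    The map lists the original 1-based coordinates of the retained columns
    so dropped sites can be audited.  Raises if nothing survives.
    """
    seqs = a.sequences()
    keep = [
        i for i in range(a.length) if all(s[i] in _ACGT for s in seqs)
    ]
    if not keep:
        raise ValueError("column filtering removed every column")
    records = [
        SequenceRecord(
            seq_id=r.seq_id,
            species=r.species,
            population=r.population,
            sequence="".join(r.sequence[i] for i in keep),
        )
        for r in a
    ]
    return AlignedSet(records), [i + 1 for i in keep]


def collapse(a: AlignedSet) -> list[Haplotype]:
    """Partition records into haplotypes by exact sequence identity.

    Input must already be filtered to {A,C,G,T}.  Haplotype ids are
    assigned deterministically by (frequency desc, first member id), so the
    partition — and the ids — are invariant under input order.
    """
    bad = [r.seq_id for r in a if set(r.sequence) - _ACGT]
    if bad:
        raise ValueError(f"unfiltered characters in: {bad}; run filter_columns first")
    by_seq: dict[str, list[SequenceRecord]] = {}
    for r in a:
        by_seq.setdefault(r.sequence, []).append(r)
    groups = sorted(
        by_seq.items(), key=lambda kv: (-len(kv[1]), min(r.seq_id for r in kv[1]))
    )
    haps = []
    for i, (seq, members) in enumerate(groups, start=1):
        members = sorted(members, key=lambda r: r.seq_id)
        pop_counts: dict[str, int] = {}
        for r in members:
            key = r.population or ""
            pop_counts[key] = pop_counts.get(key, 0) + 1
        haps.append(
            Haplotype(
                hap_id=f"H{i}",
                sequence=seq,
                members=[r.seq_id for r in members],
                groups=pop_counts,
            )
        )
    return haps


def hamming(x: str, y: str) -> int:
    if len(x) != len(y):
        raise ValueError("unequal lengths")
    return sum(a != b for a, b in zip(x, y))


def build_msn(haps: Sequence[Haplotype]) -> nx.Graph:
    """Minimum spanning network over haplotypes.

    Nodes are hap_ids (attributes: frequency, members, groups); each edge
    carries ``steps``, the exact Hamming distance of its endpoints.  The
    edge set is the union of all minimum spanning trees of the complete
    Hamming graph: processing weights in ascending order, an edge is kept
    iff its endpoints lie in different components of the strictly-cheaper
    subgraph.
    """
    if not haps:
        raise ValueError("no haplotypes")
    g = nx.Graph()
    for h in haps:
        g.add_node(h.hap_id, frequency=h.frequency, members=list(h.members),
                   groups=dict(h.groups))
    if len(haps) == 1:
        return g
    edges = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            w = hamming(haps[i].sequence, haps[j].sequence)
            edges.append((w, haps[i].hap_id, haps[j].hap_id))
    edges.sort()

    parent = {h.hap_id: h.hap_id for h in haps}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    k = 0
    while k < len(edges):
        w = edges[k][0]
        batch = []
        while k < len(edges) and edges[k][0] == w:
            batch.append(edges[k])
            k += 1
        # membership test against components formed by strictly smaller weights
        kept = [(u, v) for _, u, v in batch if find(u) != find(v)]
        for u, v in kept:
            g.add_edge(u, v, steps=w)
        for u, v in kept:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[max(ru, rv)] = min(ru, rv)
    return g


def group_separation(
    a: AlignedSet | Sequence[Haplotype],
    group_a: Iterable[str],
    group_b: Iterable[str],
    by: str = "population",
) -> int:
    """Minimum mutational steps between two labelled groups.

    ``group_a``/``group_b`` are population (or species, ``by="species"``)
    labels; the statistic is the minimum Hamming distance over all
    cross-group sequence pairs on the filtered columns.  Groups sharing a
    haplotype are separated by 0 steps.
    """
    ga, gb = set(group_a), set(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")

    if isinstance(a, AlignedSet):
        filtered, _ = filter_columns(a)

        def label(r: SequenceRecord) -> str | None:
            return r.population if by == "population" else r.species

        seqs_a = [r.sequence for r in filtered if label(r) in ga]
        seqs_b = [r.sequence for r in filtered if label(r) in gb]
    else:
        # haplotypes: group membership from the per-population counts
        seqs_a = [h.sequence for h in a if any(k in ga for k, c in h.groups.items() if c)]
        seqs_b = [h.sequence for h in a if any(k in gb for k, c in h.groups.items() if c)]
    known = ga | gb
    if not seqs_a or not seqs_b:
        empty = "A" if not seqs_a else "B"
        raise KeyError(f"no sequences labelled with group {empty} ({sorted(known)})")
    return min(hamming(x, y) for x in seqs_a for y in seqs_b)
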