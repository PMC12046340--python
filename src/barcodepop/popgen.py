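"""Nucleotide diversity and pairwise FST between labelled populations.

π is the mean over all sequence pairs of per-site differences, with
pairwise deletion of columns carrying a gap/ambiguity in either sequence.
FST follows the Hudson, Slatkin & Maddison (1992) form used by DnaSP's
common workflow:

    FST = 1 - Hw / Hb

where Hw is the unweighted average of the two within-population mean
pairwise difference counts and Hb the mean pairwise difference count
between populations.  Small negative values are possible and preserved.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distmat import k2p_distance
from .seqio import AlignedSet

__all__ = [
    "PopPair",
    "nucleotide_diversity",
    "pairwise_fst",
    "population_k2p",
    "fst_matrix",
]

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


def _diffs_and_sites(x: str, y: str) -> tuple[int, int]:
    """(differences, compared sites) under pairwise deletion."""
    diffs = sites = 0
    for a, b in zip(x, y):
        if a in _ACGT and b in _ACGT:
            sites += 1
            if a != b:
                diffs += 1
    return diffs, sites


def nucleotide_diversity(seqs: Sequence[str]) -> float:
    """π: mean over all pairs of (differences / compared sites).

    Needs >= 2 aligned sequences; raises when some pair shares no
    comparable site.
    """
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    total = 0.0
    n_pairs = 0
    for x, y in itertools.combinations(seqs, 2):
        diffs, sites = _diffs_and_sites(x, y)
        if sites == 0:
            raise ValueError("a sequence pair shares no comparable sites")
        total += diffs / sites
        n_pairs += 1
    return total / n_pairs


@dataclass(frozen=True)
class PopPair:
    """Pairwise differentiation between two labelled populations."""

    pop_a: str
    pop_b: str
    Hw: float | None  # mean within-pop pairwise differences (counts)
    Hb: float  # mean between-pop pairwise differences (counts)
    fst: float  # 1 - Hw/Hb; NaN when Hb == 0
    no_between_variation: bool = False


def _mean_pairwise_diffs(seqs: Sequence[str]) -> float:
    total = 0
    n = 0
    for x, y in itertools.combinations(seqs, 2):
        diffs, sites = _diffs_and_sites(x, y)
        if sites == 0:
            raise ValueError("a sequence pair shares no comparable sites")
        total += diffs
        n += 1
    return total / n


def pairwise_fst(
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    labels: tuple[str, str] = ("A", "B"),
) -> PopPair:
    """Hudson–Slatkin–Maddison FST between two sequence samples.

    Populations of size 1 contribute no within term: Hw averages over the
    populations with >= 2 sequences (logged).  Hb = 0 makes FST undefined
    (NaN, flagged "no between-population variation").
    """
    if not pop_a or not pop_b:
        raise ValueError("both populations must be non-empty")
    hb_total = 0
    for x in pop_a:
        for y in pop_b:
            diffs, sites = _diffs_and_sites(x, y)
            if sites == 0:
                raise ValueError("a sequence pair shares no comparable sites")
            hb_total += diffs
    Hb = hb_total / (len(pop_a) * len(pop_b))

    within = []
    for name, pop in zip(labels, (pop_a, pop_b)):
        if len(pop) >= 2:
            within.append(_mean_pairwise_diffs(pop))
        else:
            logger.info("population %s has a single sequence; no within term", name)
    Hw = float(np.mean(within)) if within else None

    if Hb == 0.0:
        return PopPair(labels[0], labels[1], Hw, Hb, float("nan"),
                       no_between_variation=True)
    if Hw is None:
        raise ValueError(
            "FST undefined: neither population has >= 2 sequences"
        )
    return PopPair(labels[0], labels[1], Hw, Hb, 1.0 - Hw / Hb)


def population_k2p(pop_a: Sequence[str], pop_b: Sequence[str]) -> float:
    """Mean K2P distance over all between-population sequence pairs."""
    if not pop_a or not pop_b:
        raise ValueError("both populations must be non-empty")
    vals = []
    for x in pop_a:
        for y in pop_b:
            r = k2p_distance(x, y)
            if r.saturated:
                raise ValueError("saturated K2P pair between populations")
            vals.append(r.d)
    return float(np.mean(vals))


def fst_matrix(a: AlignedSet, group_by: str = "population") -> pd.DataFrame:
    """Lower-triangle FST matrix over all labelled groups in an alignment.

    ``group_by`` is "population" or "species"; records without the label
    are ignored.  Mirrors the layout of published pairwise-FST tables.
    """
    groups: dict[str, list[str]] = {}
    for r in a:
        key = r.population if group_by == "population" else r.species
        if key:
            groups.setdefault(key, []).append(r.sequence)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 labelled groups")
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for i, gi in enumerate(names):
        for j in range(i):
            gj = names[j]
            pair = pairwise_fst(groups[gi], groups[gj], labels=(gi, gj))
            out.loc[gi, gj] = pair.fst
    return out
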