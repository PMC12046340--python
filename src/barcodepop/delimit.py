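"""Species-confirmation criteria and the per-species delimitation report.

A species is confirmed by its barcodes when (a) it is monophyletic on the
tree and (b) it shares no identical barcode with another species.
Additional screening flags mark candidates for closer inspection: a deep
intraspecific split (maximum intraspecific distance above a threshold,
default 2%) and low divergence from the nearest neighbour (below a
threshold, default 1%).  Thresholds are conventions for flagging, not
decision rules, and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distmat import DistanceSummary
from .hapnet import collapse, filter_columns
from .njtree import PhyloTree, is_monophyletic
from .seqio import AlignedSet

__all__ = ["Thresholds", "shared_barcodes", "verdict", "delimit"]

VERDICTS = (
    "confirmed",
    "flag-paraphyly",
    "flag-shared-barcode",
    "flag-deep-split",
    "flag-low-divergence",
    "n<2",
)


@dataclass(frozen=True)
class Thresholds:
    """Flagging thresholds, as distance proportions."""

    deep_split: float = 0.02  # max intraspecific distance above this -> flag
    low_divergence: float = 0.01  # nearest-neighbour distance below this -> flag


def shared_barcodes(a: AlignedSet) -> dict[str, set[str]]:
    """Species sharing an identical (column-filtered) haplotype.

    Identity is exact equality after dropping columns with any
    gap/ambiguity — not K2P distance zero, which pairwise deletion could
    produce from non-identical sequences.  The relation is symmetric;
    species sharing nothing are absent from the map.
    """
    filtered, _ = filter_columns(a)
    by_id = {r.seq_id: r.species for r in a}
    out: dict[str, set[str]] = {}
    for hap in collapse(filtered):
        species = {by_id[m] for m in hap.members}
        if len(species) > 1:
            for sp in species:
                out.setdefault(sp, set()).update(species - {sp})
    return out


def verdict(
    monophyletic: bool,
    shares_barcode: bool,
    deep_split: bool,
    low_divergence: bool,
    single_sequence: bool,
) -> str:
    """Single verdict from the four flags (priority order below).

    "confirmed" requires monophyly AND no shared barcode; failures of the
    two confirmation criteria outrank the screening flags, which outrank
    the n<2 placeholder for single-sequence species.  Barcode sharing
    outranks paraphyly: identical cross-species haplotypes force an
    arbitrary resolution of zero-length branches, so the sharing is the
    diagnostic signal and the paraphyly its consequence.
    """
    if shares_barcode:
        return "flag-shared-barcode"
    if not monophyletic:
        return "flag-paraphyly"
    if deep_split:
        return "flag-deep-split"
    if low_divergence:
        return "flag-low-divergence"
    if single_sequence:
        return "n<2"
    return "confirmed"


def delimit(
    a: AlignedSet,
    tree: PhyloTree,
    summary: DistanceSummary,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-species delimitation report.

    Columns: monophyly (+ bootstrap of the supporting edge), barcode
    sharing partners, max intraspecific %, nearest-neighbour species and
    distance %, and the verdict.  Deterministic and invariant under record
    order.
    """
    sharing = shared_barcodes(a)
    by_species = a.by_species()
    per_sp = summary.per_species.set_index("species")
    rows = []
    for sp in sorted(by_species):
        tips = [r.seq_id for r in by_species[sp]]
        mono, edge = is_monophyletic(tree, tips)
        support = edge.support if edge is not None else None
        shared_with = sorted(sharing.get(sp, set()))
        info = per_sp.loc[sp]
        max_intra = float(info["intra_max"])
        nn_dist = float(info["nn_dist"])
        n = int(info["n"])
        deep = (not np.isnan(max_intra)) and max_intra > thresholds.deep_split
        low = (not np.isnan(nn_dist)) and nn_dist < thresholds.low_divergence
        rows.append(
            {
                "species": sp,
                "n": n,
                "monophyletic": mono,
                "support": support,
                "shared_with": ";".join(shared_with),
                "max_intra_pct": round(max_intra * 100, 2) if not np.isnan(max_intra) else None,
                "nn_species": info["nn_species"],
                "nn_dist_pct": round(nn_dist * 100, 2) if not np.isnan(nn_dist) else None,
                "verdict": verdict(
                    monophyletic=mono,
                    shares_barcode=bool(shared_with),
                    deep_split=deep,
                    low_divergence=low,
                    single_sequence=n < 2,
                ),
            }
        )
    return pd.DataFrame(rows)
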