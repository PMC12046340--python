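"""Site-degeneracy diversity and the purifying-selection regression.

Protein-coding barcode alignments are classified per codon position under
the vertebrate mitochondrial code (NCBI translation table 2: AGA/AGG are
stops, ATA is Met, TGA is Trp).  A position is 0-fold degenerate when
every nucleotide change alters the encoded amino acid and 4-fold when none
does; π at 0-fold sites (π0) measures amino-acid-changing variation while
π at 4-fold sites (π4) is silent and proxies 2·Ne·µ.  Under Ne-scaled
purifying selection, species with larger effective population sizes purge
relatively more 0-fold variation, so log(π0/π4) declines with log(π4) —
the regression this module fits (OLS, with Kendall's rank correlation
alongside).

Note the construction shares π4 between the two axes, which induces some
negative correlation even under a neutral null; the fitted slope is
reported exactly as defined, not "corrected", and the test suite
quantifies the null by simulation.
"""

from __future__ import annotations

import logging
import math
from functools import lru_cache
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .popgen import nucleotide_diversity

__all__ = [
    "CodonFrame",
    "DiversityRecord",
    "RegressionResult",
    "VERTEBRATE_MITO",
    "translate_codon",
    "detect_frame",
    "classify_degeneracy",
    "classify_sites",
    "site_diversity",
    "selection_regression",
]

logger = logging.getLogger(__name__)

_ACGT = "ACGT"
_ACGT_SET = frozenset(_ACGT)

#: NCBI translation table 2 (vertebrate mitochondrial).
VERTEBRATE_MITO = CodonTable.unambiguous_dna_by_id[2]
_STOPS = frozenset(VERTEBRATE_MITO.stop_codons)

CLASS_0FOLD = "0-fold"
CLASS_2FOLD = "2-fold"
CLASS_3FOLD = "3-fold"
CLASS_4FOLD = "4-fold"
CLASS_EXCLUDED = "excluded"

_FOLD_NAMES = {0: CLASS_0FOLD, 1: CLASS_2FOLD, 2: CLASS_3FOLD, 3: CLASS_4FOLD}


def translate_codon(codon: str) -> str | None:
    """Amino acid under table 2, or None for a stop codon."""
    if codon in _STOPS:
        return None
    return VERTEBRATE_MITO.forward_table[codon]


@lru_cache(maxsize=None)
def classify_degeneracy(codon: str, position: int) -> str:
    """Degeneracy class of one codon position (1-3) under table 2.

    The class counts how many of the 3 alternative nucleotides at that
    position preserve the encoded amino acid: 0 preserved -> 0-fold, all 3
    -> 4-fold, else 2-fold/3-fold.  A change producing a stop codon never
    preserves the amino acid.  Stop codons and codons with ambiguity are
    "excluded".
    """
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    if len(codon) != 3 or set(codon) - _ACGT_SET:
        return CLASS_EXCLUDED
    aa = translate_codon(codon)
    if aa is None:
        return CLASS_EXCLUDED
    i = position - 1
    preserved = 0
    for base in _ACGT:
        if base == codon[i]:
            continue
        alt = codon[:i] + base + codon[i + 1:]
        if translate_codon(alt) == aa:
            preserved += 1
    return _FOLD_NAMES[preserved]


def consensus_sequence(seqs: Sequence[str]) -> str:
    """Majority-rule consensus; ties pick the alphabetically first base.

    Columns with no unambiguous base become "N".
    """
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    out = []
    for i in range(L):
        counts: dict[str, int] = {}
        for s in seqs:
            c = s[i]
            if c in _ACGT_SET:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("N")
        else:
            out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


@dataclass(frozen=True)
class CodonFrame:
    """Chosen reading-frame offset with per-candidate stop counts."""

    offset: int  # 0, 1 or 2
    stop_counts: tuple[int, int, int]


class FrameDetectionError(ValueError):
    """No unique stop-minimal reading frame; supply --frame explicitly."""


def _count_stops(seq: str, offset: int) -> int:
    stops = 0
    for start in range(offset, len(seq) - 2, 3):
        codon = seq[start:start + 3]
        if set(codon) - _ACGT_SET:
            continue
        if codon in _STOPS:
            stops += 1
    return stops


def detect_frame(seqs: Sequence[str]) -> CodonFrame:
    """Pick the reading frame of a species' sequences by stop counting.

    Translates the majority consensus in each of the three offsets under
    table 2 and returns the unique offset with the fewest internal stops.
    A tie, or a minimum above zero, is an error demanding an explicit
    frame.
    """
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs[0]) < 30:
        raise ValueError("sequences too short for frame detection (< 30 nt)")
    cons = consensus_sequence(seqs)
    counts = tuple(_count_stops(cons, off) for off in range(3))
    best = min(counts)
    winners = [off for off, c in enumerate(counts) if c == best]
    if len(winners) > 1:
        raise FrameDetectionError(
            f"ambiguous reading frame (stop counts {counts}); specify the frame"
        )
    if best > 0:
        raise FrameDetectionError(
            f"no stop-free reading frame (stop counts {counts}); specify the frame"
        )
    return CodonFrame(offset=winners[0], stop_counts=counts)


def classify_sites(consensus: str, frame: int) -> list[str]:
    """Per-column degeneracy classes of a consensus sequence.

    Columns outside complete in-frame codons, or in codons containing
    ambiguity or a stop, are "excluded".
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    classes = [CLASS_EXCLUDED] * len(consensus)
    for start in range(frame, len(consensus) - 2, 3):
        codon = consensus[start:start + 3]
        for pos in (1, 2, 3):
            classes[start + pos - 1] = classify_degeneracy(codon, pos)
    return classes


@dataclass
class DiversityRecord:
    """Per-species diversity at 0-fold and 4-fold degenerate sites.

    ``included`` marks species usable for the selection regression:
    species with zero diversity at either site class are excluded.
    """

    species: str
    pi0: float
    pi4: float
    n0: int
    n4: int
    included: bool
    reason: str = ""


def site_diversity(
    species: str,
    seqs: Sequence[str],
    frame: int | None = None,
) -> DiversityRecord:
    """π0/π4 for one species' aligned sequences.

    Degeneracy is assigned on the species majority consensus; columns
    whose class differs among the codons actually observed in the species
    (or that fall in an observed stop codon) are excluded, so polymorphic
    codon context never mixes classes.  π is computed by restricting the
    alignment to each class's columns (pairwise deletion within), with
    per-site normalization by the class site counts n0/n4.
    """
    if len(seqs) < 2:
        raise ValueError("site diversity needs >= 2 sequences")
    if frame is None:
        frame = detect_frame(seqs).offset
    cons = consensus_sequence(seqs)
    classes = classify_sites(cons, frame)

    # polymorphic-context exclusion: every observed ACGT codon must agree
    for start in range(frame, len(cons) - 2, 3):
        observed = {s[start:start + 3] for s in seqs}
        observed = {c for c in observed if not set(c) - _ACGT_SET}
        for pos in (1, 2, 3):
            col = start + pos - 1
            if classes[col] == CLASS_EXCLUDED:
                continue
            member_classes = {classify_degeneracy(c, pos) for c in observed}
            member_classes.add(classes[col])
            if len(member_classes) > 1:
                classes[col] = CLASS_EXCLUDED

    cols0 = [i for i, c in enumerate(classes) if c == CLASS_0FOLD]
    cols4 = [i for i, c in enumerate(classes) if c == CLASS_4FOLD]
    n0, n4 = len(cols0), len(cols4)
    if n0 == 0 or n4 == 0:
        return DiversityRecord(species, math.nan, math.nan, n0, n4,
                               included=False, reason="no 0-fold or 4-fold sites")

    def restricted_pi(cols: list[int]) -> float:
        sub = ["".join(s[i] for i in cols) for s in seqs]
        return nucleotide_diversity(sub)

    pi0 = restricted_pi(cols0)
    pi4 = restricted_pi(cols4)
    included = pi0 > 0 and pi4 > 0
    reason = "" if included else "zero diversity at a site class"
    return DiversityRecord(species, pi0, pi4, n0, n4, included, reason)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of log(π0/π4) on log(π4) plus Kendall's rank correlation."""

    slope: float
    intercept: float
    slope_p: float
    tau: float
    tau_p: float
    n: int
    log_base: float = 10.0


def selection_regression(
    records: Sequence[DiversityRecord], log_base: float = 10.0
) -> RegressionResult:
    """Fit the Ne-scaled purifying-selection relationship across species.

    Uses only records with ``included=True`` (π0 > 0 and π4 > 0); needs at
    least 3.  ``log_base`` defaults to 10; slope sign and tau are
    base-invariant.  A degenerate design (all π4 equal) is an error.
    """
    used = [r for r in records if r.included]
    if len(used) < 3:
        raise ValueError(f"need >= 3 included species, got {len(used)}")
    lb = math.log(log_base)
    x = np.array([math.log(r.pi4) / lb for r in used])
    y = np.array([math.log(r.pi0 / r.pi4) / lb for r in used])
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all pi4 values identical")
    fit = stats.linregress(x, y)
    tau = stats.kendalltau(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_p=float(fit.pvalue),
        tau=float(tau.statistic),
        tau_p=float(tau.pvalue),
        n=len(used),
        log_base=log_base,
    )
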