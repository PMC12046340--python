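"""Kimura 2-parameter distances and barcode-gap summaries.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T; proportion P) from transversions
(proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Distances are stored as proportions and rendered as percentages (x100) in
reports.  Columns where either sequence has a non-ACGT character are
excluded per pair ("pairwise deletion") by default; a "complete" policy
restricting all pairs to universally resolved columns is also available.
Saturated pairs (non-positive log argument) yield NaN with a flag and are
excluded from summaries with a logged count — clamping them would bias the
interspecific mean.

The all-pairs matrix is computed from one-hot encodings with BLAS matrix
products, so study-sized alignments (hundreds of sequences) take well
under a second; the scalar :func:`k2p_distance` performs the identical
arithmetic on a single pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import AlignedSet

__all__ = [
    "K2PResult",
    "DistanceMatrix",
    "DistanceSummary",
    "k2p_distance",
    "encode",
    "pairwise_matrix",
    "matrix_from_codes",
    "summarize",
    "barcode_gap",
]

logger = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_ACGT = {"A", "C", "G", "T"}

# base codes: A=0, G=1 (purines), C=2, T=3 (pyrimidines); 255 = gap/ambiguity
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCT"):
    _CODE[ord(_b)] = _i


def encode(seqs: Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as a (n, L) uint8 array (non-ACGT -> 255)."""
    n = len(seqs)
    L = len(seqs[0])
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(n, L)


@dataclass(frozen=True)
class K2PResult:
    """A single K2P distance with its sufficient statistics.

    ``P``/``Q`` are the transition/transversion proportions over the
    ``n_sites`` pairwise-comparable columns.  ``saturated`` marks a
    non-positive log argument; then ``d`` is NaN.
    """

    d: float
    P: float
    Q: float
    n_sites: int
    saturated: bool = False


def k2p_distance(x: str, y: str) -> K2PResult:
    """K2P distance between two equal-length aligned sequences.

    Comparison is restricted to columns where both characters are in
    {A,C,G,T}.  Raises ``ValueError`` when no column is comparable.
    """
    if len(x) != len(y):
        raise ValueError(f"unequal sequence lengths: {len(x)} vs {len(y)}")
    n = ts = tv = 0
    for a, b in zip(x, y):
        if a not in _ACGT or b not in _ACGT:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P = ts / n
    Q = tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(d=math.nan, P=P, Q=Q, n_sites=n, saturated=True)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d=d, P=P, Q=Q, n_sites=n)


@dataclass
class DistanceMatrix:
    """Symmetric K2P matrix over an aligned set.

    ``d[i, i] = 0``; NaN entries are allowed only where ``saturated`` is
    True (they are flagged, never silently dropped).
    """

    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray  # boolean mask, same shape as d

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    @property
    def n_saturated_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(self.saturated[iu].sum())

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            d=self.d[np.ix_(idx, idx)],
            saturated=self.saturated[np.ix_(idx, idx)],
        )


def matrix_from_codes(codes: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    """All-pairs K2P from an encoded alignment (see :func:`encode`)."""
    valid = (codes < 4).astype(np.float32)
    onehot = [(codes == b).astype(np.float32) for b in range(4)]
    n_sites = valid @ valid.T
    same = sum(m @ m.T for m in onehot)
    pur = onehot[0] + onehot[1]
    pyr = onehot[2] + onehot[3]
    same_class = pur @ pur.T + pyr @ pyr.T

    n_sites = np.rint(n_sites).astype(np.int64)
    ts = np.rint(same_class - same).astype(np.int64)
    tv = np.rint(n_sites - same_class).astype(np.int64)

    off_diag = ~np.eye(len(codes), dtype=bool)
    if np.any((n_sites == 0) & off_diag):
        raise ValueError("no comparable sites for at least one pair")
    safe_n = np.where(n_sites == 0, 1, n_sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / safe_n
        Q = tv / safe_n
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        sat = ((w1 <= 0.0) | (w2 <= 0.0)) & off_diag
        d = -0.5 * np.log(np.where(w1 > 0, w1, 1.0)) - 0.25 * np.log(
            np.where(w2 > 0, w2, 1.0)
        )
    d[sat] = np.nan
    np.fill_diagonal(d, 0.0)
    m = DistanceMatrix(labels=list(labels), d=d, saturated=sat)
    if m.n_saturated_pairs:
        logger.warning("%d saturated (NaN) K2P pairs flagged", m.n_saturated_pairs)
    return m


def pairwise_matrix(a: AlignedSet, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P matrix.

    ``deletion`` is "pairwise" (per-pair exclusion of non-ACGT columns, the
    barcoding norm and the default) or "complete" (drop any column with a
    non-ACGT character in any sequence, then compare).
    """
    if len(a) < 2:
        raise ValueError("need at least 2 records")
    codes = encode(a.sequences())
    if deletion == "complete":
        keep = np.all(codes < 4, axis=0)
        if not keep.any():
            raise ValueError("complete deletion removes every column")
        codes = codes[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion!r}")
    return matrix_from_codes(codes, a.ids)


@dataclass
class DistanceSummary:
    """Intra/inter-specific decomposition of a distance matrix.

    Distances are proportions.  ``intra_mean`` is the all-pairs mean over
    conspecific comparisons; ``intra_mean_species`` is the mean of
    per-species averages (both are reported because published summaries are
    often ambiguous about which estimator they used).  Species with fewer
    than two sequences carry no intraspecific entry.
    """

    per_species: pd.DataFrame  # species, n, intra_mean, intra_max, nn_species, nn_dist
    intra_mean: float | None
    intra_mean_species: float | None
    intra_range: tuple[float, float] | None
    inter_mean: float | None
    inter_range: tuple[float, float] | None
    n_intra_pairs: int
    n_inter_pairs: int
    n_saturated_excluded: int
    intra_hist: pd.DataFrame | None = None
    inter_hist: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "intra_mean": self.intra_mean,
            "intra_mean_species": self.intra_mean_species,
            "intra_range": self.intra_range,
            "inter_mean": self.inter_mean,
            "inter_range": self.inter_range,
            "n_intra_pairs": self.n_intra_pairs,
            "n_inter_pairs": self.n_inter_pairs,
            "n_saturated_excluded": self.n_saturated_excluded,
        }


def _histogram(values: np.ndarray, bin_width_pct: float) -> pd.DataFrame:
    pct = values * 100.0
    top = max(bin_width_pct, float(np.ceil(pct.max() / bin_width_pct)) * bin_width_pct)
    edges = np.arange(0.0, top + bin_width_pct / 2, bin_width_pct)
    counts, edges = np.histogram(pct, bins=edges)
    return pd.DataFrame(
        {"bin_left_pct": edges[:-1], "bin_right_pct": edges[1:], "count": counts}
    )


def summarize(
    m: DistanceMatrix,
    species: Sequence[str],
    bin_width_pct: float = 1.0,
) -> DistanceSummary:
    """Decompose a distance matrix into intra/inter-specific summaries.

    ``species`` gives the species label for each matrix row (same order as
    ``m.labels``).  Saturated pairs are excluded from every mean with a
    logged count.
    """
    species = list(species)
    if len(species) != len(m.labels):
        raise ValueError("species labels must match matrix labels")
    sp = np.asarray(species)
    n = len(sp)
    iu = np.triu_indices(n, k=1)
    same_sp = (sp[iu[0]] == sp[iu[1]])
    vals = m.d[iu]
    sat = m.saturated[iu]
    n_sat = int(sat.sum())
    if n_sat:
        logger.warning("excluded %d saturated pairs from distance summary", n_sat)

    intra = vals[same_sp & ~sat]
    inter = vals[~same_sp & ~sat]

    rows = []
    order = sorted(set(species))
    for sp_name in order:
        mask = sp == sp_name
        idx = np.flatnonzero(mask)
        # conspecific block
        if len(idx) >= 2:
            block = m.d[np.ix_(idx, idx)]
            bsat = m.saturated[np.ix_(idx, idx)]
            biu = np.triu_indices(len(idx), k=1)
            bvals = block[biu][~bsat[biu]]
        else:
            bvals = np.array([])
        # nearest heterospecific neighbour
        het = np.flatnonzero(~mask)
        cross = m.d[np.ix_(idx, het)]
        csat = m.saturated[np.ix_(idx, het)]
        cvals = cross[~csat]
        if cvals.size:
            flat = np.where(csat, np.inf, cross)
            pos = np.unravel_index(np.argmin(flat), flat.shape)
            nn_dist = float(flat[pos])
            nn_species = species[het[pos[1]]]
        else:
            nn_dist, nn_species = np.nan, None
        rows.append(
            {
                "species": sp_name,
                "n": int(mask.sum()),
                "intra_mean": float(bvals.mean()) if bvals.size else np.nan,
                "intra_max": float(bvals.max()) if bvals.size else np.nan,
                "nn_species": nn_species,
                "nn_dist": nn_dist,
            }
        )
    per_species = pd.DataFrame(rows)
    sp_means = per_species["intra_mean"].dropna()

    if intra.size == 0:
        logger.warning("no conspecific pairs: intraspecific summary empty")
    return DistanceSummary(
        per_species=per_species,
        intra_mean=float(intra.mean()) if intra.size else None,
        intra_mean_species=float(sp_means.mean()) if len(sp_means) else None,
        intra_range=(float(intra.min()), float(intra.max())) if intra.size else None,
        inter_mean=float(inter.mean()) if inter.size else None,
        inter_range=(float(inter.min()), float(inter.max())) if inter.size else None,
        n_intra_pairs=int(intra.size),
        n_inter_pairs=int(inter.size),
        n_saturated_excluded=n_sat,
        intra_hist=_histogram(intra, bin_width_pct) if intra.size else None,
        inter_hist=_histogram(inter, bin_width_pct) if inter.size else None,
    )


def barcode_gap(s: DistanceSummary) -> tuple[pd.DataFrame, float | None]:
    """Per-species barcode-gap report plus the global gap statistic.

    The global gap is mean interspecific minus mean intraspecific distance.
    A species "has a gap" when its nearest-neighbour (minimum
    heterospecific) distance strictly exceeds its maximum intraspecific
    distance; ties are broken conservatively (no gap).  Species with fewer
    than two sequences are flagged ``n<2``.
    """
    report = s.per_species.copy()
    flags = []
    for _, row in report.iterrows():
        if row["n"] < 2 or np.isnan(row["intra_max"]):
            flags.append("n<2")
        elif np.isnan(row["nn_dist"]):
            flags.append("no-heterospecific")
        elif row["nn_dist"] > row["intra_max"]:
            flags.append("gap")
        else:
            flags.append("no-gap")
    report["gap_flag"] = flags
    global_gap = (
        s.inter_mean - s.intra_mean
        if s.inter_mean is not None and s.intra_mean is not None
        else None
    )
    return report, global_gap
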