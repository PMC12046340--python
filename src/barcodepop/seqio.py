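"""Reading, validation and writing of aligned barcode data.

The analysis operates on a multiple sequence alignment of protein-coding
mtDNA barcodes (FASTA, IUPAC codes, ``-`` for gaps) joined to a specimen
metadata table (TSV with columns ``seq_id``, ``species`` and optionally
``population``).  This module owns that plumbing plus all tabular/graph
output writers used downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "IUPAC_DNA",
    "SequenceRecord",
    "AlignedSet",
    "read_fasta",
    "write_fasta",
    "join_metadata",
    "read_metadata",
    "species_census",
    "write_distance_matrix",
    "write_edge_list",
    "write_graphml",
    "write_json",
]

#: Allowed characters: the four bases, IUPAC ambiguity codes, N and the gap.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

BASES = frozenset("ACGT")


class SeqFormatError(ValueError):
    """Malformed FASTA/metadata input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned barcode sequence with its specimen metadata."""

    seq_id: str
    species: str
    sequence: str
    population: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqFormatError(f"empty sequence for {self.seq_id!r}")
        if not self.species:
            raise SeqFormatError(f"empty species label for {self.seq_id!r}")


@dataclass
class AlignedSet:
    """An alignment of :class:`SequenceRecord` sharing one length.

    Records keep input order.  ``length`` is the number of alignment
    columns; all per-species statistics downstream require at least two
    records for the species in question.
    """

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqFormatError("empty aligned set")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise SeqFormatError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        ids = [r.seq_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqFormatError(f"duplicate seq_id(s): {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    @property
    def species_labels(self) -> list[str]:
        return [r.species for r in self.records]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def by_species(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {}
        for r in self.records:
            out.setdefault(r.species, []).append(r)
        return out

    def subset(self, seq_ids: Iterable[str]) -> "AlignedSet":
        wanted = set(seq_ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise KeyError(f"unknown seq_id(s): {sorted(unknown)}")
        return AlignedSet([r for r in self.records if r.seq_id in wanted])

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single characters."""
        return np.array([list(r.sequence) for r in self.records])


def _validate_sequence(seq_id: str, seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in IUPAC_DNA:
            raise SeqFormatError(
                f"non-IUPAC character {ch!r} at position {pos} in {seq_id!r}"
            )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(seq_id, sequence)`` pairs, input order kept.

    The seq_id is the header token before the first whitespace (GenBank-style
    deflines tolerated); sequences are upper-cased.  Duplicate ids and
    non-IUPAC characters are hard errors.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id
        if seq_id in seen:
            raise SeqFormatError(f"duplicate seq_id {seq_id!r} in {path}")
        seen.add(seq_id)
        out.append((seq_id, _validate_sequence(seq_id, str(rec.seq))))
    if not out:
        raise SeqFormatError(f"no FASTA records in {path}")
    return out


def write_fasta(records: Iterable[SequenceRecord] | AlignedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.seq_id}\n{r.sequence}\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata TSV (header row mandatory)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"seq_id", "species"} - set(table.columns)
    if missing:
        raise SeqFormatError(f"metadata missing column(s): {sorted(missing)}")
    return table


def join_metadata(
    seqs: Sequence[tuple[str, str]], table: pd.DataFrame | str | Path
) -> AlignedSet:
    """Join FASTA records to the metadata table into an :class:`AlignedSet`.

    Every seq_id must appear exactly once in the table; sequence content is
    never altered and record order follows the FASTA.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_metadata(table)
    if table["seq_id"].duplicated().any():
        dup = sorted(table.loc[table["seq_id"].duplicated(), "seq_id"])
        raise SeqFormatError(f"duplicate seq_id(s) in metadata: {dup}")
    meta = table.set_index("seq_id")
    missing = [sid for sid, _ in seqs if sid not in meta.index]
    if missing:
        raise SeqFormatError(f"seq_id(s) missing from metadata: {missing}")
    has_pop = "population" in meta.columns
    records = []
    for sid, seq in seqs:
        row = meta.loc[sid]
        pop = row["population"] if has_pop and pd.notna(row["population"]) else None
        records.append(
            SequenceRecord(seq_id=sid, species=row["species"], sequence=seq,
                           population=pop)
        )
    return AlignedSet(records)


def load_aligned_set(fasta: str | Path, metadata: str | Path) -> AlignedSet:
    """Convenience: read FASTA + metadata TSV and join them."""
    return join_metadata(read_fasta(fasta), metadata)


def species_census(a: AlignedSet) -> tuple[pd.DataFrame, dict]:
    """Per-species sequence counts plus dataset totals.

    Returns a table (species, n_sequences) and a totals dict with
    ``n_sequences``, ``n_species``, ``mean_per_species`` (2 decimals) and the
    (min, max) range of per-species counts.
    """
    counts = pd.Series(a.species_labels).value_counts().sort_index()
    table = counts.rename_axis("species").reset_index(name="n_sequences")
    totals = {
        "n_sequences": int(counts.sum()),
        "n_species": int(len(counts)),
        "mean_per_species": round(float(counts.mean()), 2),
        "range": (int(counts.min()), int(counts.max())),
    }
    return table, totals


# ---------------------------------------------------------------------------
# Output writers (all downstream modules serialize through these)
# ---------------------------------------------------------------------------

def write_distance_matrix(labels: Sequence[str], d: np.ndarray, path: str | Path) -> None:
    """Full symmetric matrix as TSV, labels in row/column 0, %.6f proportions."""
    df = pd.DataFrame(d, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.6f")


def write_edge_list(graph: nx.Graph, path: str | Path, weight: str = "steps") -> None:
    rows = [
        {"hap_a": u, "hap_b": v, weight: data[weight]}
        for u, v, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["hap_a", "hap_b", weight]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    g = nx.Graph()
    for n, data in graph.nodes(data=True):
        g.add_node(n, **{k: _graphml_safe(v) for k, v in data.items()})
    for u, v, data in graph.edges(data=True):
        g.add_edge(u, v, **{k: _graphml_safe(v2) for k, v2 in data.items()})
    nx.write_graphml(g, str(path))


def _graphml_safe(value):
    if isinstance(value, (str, int, float, bool)):
        return value
    return json.dumps(value)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
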