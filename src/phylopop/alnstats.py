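"""Alignment utilities: occupancy cleaning, concatenation, summary statistics.

An :class:`Alignment` is a rectangular character matrix over {A,C,G,T,-,N}
keyed by row name.  'N' is treated as missing (like '-') for both column
occupancy and parsimony informativeness by default; both functions take a
switch because conventions differ between tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import GeneTree

__all__ = [
    "Alignment",
    "Partition",
    "read_fasta",
    "write_fasta",
    "clean_columns",
    "concatenate",
    "split_by_partitions",
    "parsimony_informative_sites",
    "tree_length",
    "partition_text",
]

_MISSING = {"-", "N"}


@dataclass
class Alignment:
    """Named rows of equal length; insertion order is preserved."""

    rows: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.rows.values()], dtype="U1")

    def subset_columns(self, keep: np.ndarray) -> "Alignment":
        return Alignment({name: "".join(np.array(list(s), dtype="U1")[keep]) for name, s in self.rows.items()})


@dataclass
class Partition:
    """1-based inclusive span of one gene in a concatenated alignment."""

    gene_id: str
    start: int
    end: int


def read_fasta(path) -> Alignment:
    rows = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate row name {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    return Alignment(rows)


def write_fasta(a: Alignment, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in a.rows.items()]
    SeqIO.write(records, str(path), "fasta")


def clean_columns(a: Alignment, min_occupancy: float = 0.10, treat_n_as_missing: bool = True) -> Alignment:
    """Keep columns whose non-missing fraction is >= ``min_occupancy``."""
    if not 0 < min_occupancy <= 1:
        raise ValueError("min_occupancy must be in (0, 1]")
    if not a.rows or a.length == 0:
        return Alignment(dict(a.rows))
    m = a.matrix()
    missing = m == "-"
    if treat_n_as_missing:
        missing |= m == "N"
    occupancy = 1.0 - missing.mean(axis=0)
    keep = occupancy >= min_occupancy - 1e-12
    return a.subset_columns(keep)


def concatenate(alns) -> tuple[Alignment, list[Partition]]:
    """Concatenate (gene_id, Alignment) pairs; absent rows are gap-filled.

    Returns the supermatrix and the partitions tiling it.  Duplicate gene
    ids are an error.
    """
    pairs = list(alns.items()) if isinstance(alns, dict) else list(alns)
    if not pairs:
        raise ValueError("need at least one alignment")
    seen = set()
    for gene_id, _ in pairs:
        if gene_id in seen:
            raise ValueError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
    names: list[str] = []
    for _, a in pairs:
        for name in a.rows:
            if name not in names:
                names.append(name)
    chunks = {name: [] for name in names}
    partitions = []
    offset = 0
    for gene_id, a in pairs:
        glen = a.length
        partitions.append(Partition(gene_id, offset + 1, offset + glen))
        for name in names:
            chunks[name].append(a.rows.get(name, "-" * glen))
        offset += glen
    return Alignment({name: "".join(parts) for name, parts in chunks.items()}), partitions


def split_by_partitions(a: Alignment, partitions) -> list[tuple[str, Alignment]]:
    """Inverse of :func:`concatenate` (rows gap-padded where absent)."""
    out = []
    for p in partitions:
        out.append((p.gene_id, Alignment({name: s[p.start - 1 : p.end] for name, s in a.rows.items()})))
    return out


def partition_text(partitions) -> str:
    """RAxML-style partition lines: ``DNA, gene1 = 1-100``."""
    return "\n".join(f"DNA, {p.gene_id} = {p.start}-{p.end}" for p in partitions) + "\n"


def parsimony_informative_sites(a: Alignment, treat_n_as_missing: bool = True) -> int:
    """Columns with >= 2 distinct non-missing states each seen in >= 2 rows."""
    if not a.rows or a.length == 0:
        return 0
    missing = _MISSING if treat_n_as_missing else {"-"}
    m = a.matrix()
    count = 0
    for j in range(m.shape[1]):
        states = Counter(c for c in m[:, j] if c not in missing)
        if sum(1 for v in states.values() if v >= 2) >= 2:
            count += 1
    return count


def tree_length(t: GeneTree) -> float:
    """Sum of all branch lengths (root-independent)."""
    return t.total_length()
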