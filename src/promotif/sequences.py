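"""TSS-anchored upstream (promoter) sequences.

Coordinate convention used throughout the package: sequences are written
5'->3' on the sense strand and end at the base immediately 5' of the
transcription start site (TSS).  The TSS itself is position 0 and is not
part of the sequence; the final base of a record sits at position -1, so a
full-length record of M bases covers the inclusive interval [-M, -1].
String index i (0-based) maps to TSS-relative position i - M.  All
reported intervals are inclusive on both ends: [-119, -111] spans 9 bp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import ValidationError

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N).

    Applying the function twice returns the input unchanged.
    """
    bad = set(seq) - ALPHABET
    if bad:
        raise ValidationError(
            f"illegal character(s) {sorted(bad)} in sequence for reverse_complement"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class UpstreamSequence:
    """A gene-keyed sense-strand promoter sequence anchored at the TSS."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValidationError(f"record {self.gene_id!r}: empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            i = next(i for i, ch in enumerate(seq) if ch in bad)
            raise ValidationError(
                f"record {self.gene_id!r}: illegal character {seq[i]!r} "
                f"at position {i}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def tss_position(self, index: int) -> int:
        """TSS-relative position of 0-based string index ``index``."""
        m = len(self.sequence)
        if not 0 <= index < m:
            raise IndexError(f"index {index} out of range for length {m}")
        return index - m

    def truncated(self, extent: int) -> "UpstreamSequence":
        """The 3'-most min(M, extent) bases; the last base stays at -1."""
        if extent < 1:
            raise ValidationError(f"extent must be >= 1, got {extent}")
        if len(self.sequence) <= extent:
            return self
        return UpstreamSequence(self.gene_id, self.sequence[-extent:])


@dataclass
class SequenceSet:
    """An ordered, gene-id-unique collection of upstream sequences."""

    records: list[UpstreamSequence] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        self._index: dict[str, UpstreamSequence] = {}
        for rec in self.records:
            if rec.gene_id in self._index:
                raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
            self._index[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[UpstreamSequence]:
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> UpstreamSequence:
        return self._index[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [rec.gene_id for rec in self.records]

    def subset(self, gene_ids: Iterable[str], name: str = "") -> "SequenceSet":
        """The sub-collection with the given gene ids, in this set's order.

        Every requested id must be present.
        """
        wanted = set(gene_ids)
        missing = wanted - set(self._index)
        if missing:
            raise ValidationError(
                f"gene ids not in set {self.name!r}: {sorted(missing)[:5]}"
            )
        return SequenceSet(
            [rec for rec in self.records if rec.gene_id in wanted],
            name=name or self.name,
        )

    def is_superset_of(self, other: "SequenceSet") -> bool:
        return set(other._index) <= set(self._index)


def read_fasta(path: str | os.PathLike, name: str = "") -> SequenceSet:
    """Read a (wrapped or unwrapped) multi-record FASTA of upstream sequences.

    Record ids are the first whitespace-delimited token of each header.
    Lowercase bases are upcased; duplicate ids, illegal characters and an
    empty file are errors.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(UpstreamSequence(rec.id, str(rec.seq)))
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return SequenceSet(records, name=name or os.path.basename(str(path)))


def write_fasta(sset: SequenceSet, path: str | os.PathLike) -> None:
    """Write a SequenceSet as FASTA with 60-column line wrapping."""
    recs = [
        SeqRecord(Seq(rec.sequence), id=rec.gene_id, description="")
        for rec in sset
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(recs)


def truncate_to_extent(sset: SequenceSet, extent: int) -> SequenceSet:
    """Keep only the ``extent`` bases closest to the TSS of every record.

    Records shorter than ``extent`` are kept at full length.
    """
    if extent < 1:
        raise ValidationError(f"extent must be >= 1, got {extent}")
    return SequenceSet([rec.truncated(extent) for rec in sset], name=sset.name)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text gene-id list: one id per line, '#' comments ignored."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as handle:
        for line in handle:
            token = line.split("#", 1)[0].strip()
            if not token:
                continue
            if token in seen:
                raise ValidationError(f"duplicate gene_id {token!r} in {path}")
            seen.add(token)
            out.append(token)
    if not out:
        raise ValidationError(f"no gene ids found in {path}")
    return out


def write_gene_list(gene_ids: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for gid in gene_ids:
            handle.write(f"{gid}\n")
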