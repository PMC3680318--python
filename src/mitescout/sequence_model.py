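"""Genome database model: FASTA I/O, normalization, slicing and hard masking.

Sequences are held as plain uppercase strings over {A,C,G,T,N}; lowercase
letters are uppercased and every non-ACGT character (IUPAC ambiguity codes,
gaps, anything else) becomes N during normalization.  Coordinates are 0-based
half-open everywhere inside the package; human-readable output (FASTA headers,
reports) uses 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import FormatError, ParameterError

__all__ = [
    "SequenceEntry",
    "GenomeDatabase",
    "GenomeSlice",
    "normalize_residues",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "slice_entries",
    "hard_mask",
]

# Every byte not in ACGTacgt maps to N; lowercase maps to uppercase.
_NORM = bytes(
    (b if chr(b) in "ACGTN" else (ord(chr(b).upper()) if chr(b).upper() in "ACGT" else ord("N")))
    for b in range(256)
)
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")
_VALID = frozenset("ACGTN")


def normalize_residues(raw: str) -> str:
    """Uppercase and map every non-ACGT character to N."""
    return raw.encode("latin-1", errors="replace").translate(_NORM).decode("ascii")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N.

    Raises ParameterError on characters outside {A,C,G,T,N}.
    """
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise ParameterError(f"invalid residues for reverse_complement: {bad}")
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


@dataclass(frozen=True)
class SequenceEntry:
    """One database entry (chromosome, scaffold, contig...)."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"entry {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeDatabase:
    """Ordered collection of entries with unique ids."""

    entries: list[SequenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate entry id(s): {dup}")
        self._by_id = {e.id: e for e in self.entries}

    @property
    def total_length(self) -> int:
        return sum(len(e) for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, entry_id: str) -> SequenceEntry:
        return self._by_id[entry_id]

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._by_id


@dataclass(frozen=True)
class GenomeSlice:
    """A bounded window of an entry; position i maps to parent_offset + i."""

    parent_id: str
    parent_offset: int
    residues: str
    slice_index: int

    def __len__(self) -> int:
        return len(self.residues)

    def global_coord(self, local: int) -> int:
        return self.parent_offset + local


def read_fasta(path: str | Path) -> GenomeDatabase:
    """Read a multi-FASTA file into a normalized GenomeDatabase.

    Raises FormatError for zero records, empty records or duplicate ids;
    I/O errors propagate as OSError.
    """
    path = Path(path)
    entries: list[SequenceEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate entry id: {rec.id!r}")
            seen.add(rec.id)
            residues = normalize_residues(str(rec.seq))
            if not residues:
                raise FormatError(f"entry {rec.id!r} has no residues")
            entries.append(SequenceEntry(rec.id, rec.description, residues))
    if not entries:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeDatabase(entries)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (header, sequence) pairs as FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def slice_entries(
    db: GenomeDatabase, max_slice_size: int = 100_000, overlap: int = 900
) -> list[GenomeSlice]:
    """Cut every entry into windows of at most max_slice_size nt.

    Consecutive windows of one entry overlap by `overlap` nt so that no
    element plus its TSD context can straddle a boundary undetected.
    """
    if overlap >= max_slice_size:
        raise ParameterError(
            f"overlap ({overlap}) must be smaller than max_slice_size ({max_slice_size})"
        )
    if overlap < 0 or max_slice_size <= 0:
        raise ParameterError("overlap must be >= 0 and max_slice_size > 0")
    step = max_slice_size - overlap
    slices: list[GenomeSlice] = []
    k = 0
    for entry in db:
        n = len(entry)
        start = 0
        while True:
            end = min(start + max_slice_size, n)
            slices.append(GenomeSlice(entry.id, start, entry.residues[start:end], k))
            k += 1
            if end == n:
                break
            start += step
    return slices


def hard_mask(sl: GenomeSlice, intervals: Sequence[tuple[int, int]]) -> GenomeSlice:
    """Replace the residues in 0-based half-open `intervals` with N."""
    if not intervals:
        return sl
    buf = bytearray(sl.residues, "ascii")
    n = len(buf)
    for start, end in intervals:
        if start < 0 or end > n or start > end:
            raise ParameterError(f"interval ({start}, {end}) out of slice bounds [0, {n})")
        buf[start:end] = b"N" * (end - start)
    return GenomeSlice(sl.parent_id, sl.parent_offset, buf.decode("ascii"), sl.slice_index)
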