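"""FASTA input/output and read-set containers.

A :class:`ReadSet` is the unit every comparison operates on: a labeled,
ordered collection of nucleotide reads.  Loading uppercases sequences and
rejects characters outside the ``{A, C, G, T, N}`` alphabet; descriptions
after the first whitespace in a FASTA header are kept but ignored by all
computations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: Reads shorter than this many bases are conventionally discarded before
#: any comparative analysis.
MIN_READ_LENGTH = 60


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed."""


@dataclass(frozen=True)
class Read:
    """A single nucleotide read.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header token before the first whitespace).
    sequence : str
        Uppercase nucleotide string over ``{A, C, G, T, N}``.
    description : str
        Remainder of the FASTA header, retained but never used in
        computations.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid characters {sorted(bad)!r}; "
                "allowed alphabet is A, C, G, T, N"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSet:
    """An ordered, labeled collection of reads with unique ids."""

    label: str
    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, Read] = {}
        for r in self.reads:
            if r.id in self._index:
                raise ValueError(f"duplicate read id {r.id!r} in dataset {self.label!r}")
            self._index[r.id] = r

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._index

    def get(self, read_id: str) -> Read:
        return self._index[read_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.reads]


def read_fasta(path: str | os.PathLike, label: str | None = None) -> ReadSet:
    """Load a (multi-)FASTA file into a :class:`ReadSet`.

    The header token before the first whitespace becomes the read id; the
    rest is kept as the description.  Lowercase bases are uppercased;
    characters outside ``{A, C, G, T, N}`` raise :class:`FastaParseError`,
    as do duplicate ids.  An empty file yields an empty ReadSet.

    Parameters
    ----------
    path
        FASTA file, wrapped or unwrapped.
    label
        Dataset label; defaults to the file stem.
    """
    path = os.fspath(path)
    if label is None:
        label = os.path.splitext(os.path.basename(path))[0]
    # SeqIO silently returns nothing for a file whose first non-blank line is
    # not a header; detect that case ourselves so the error names the line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header ('>'), "
                        f"got {line.strip()[:40]!r}"
                    )
                break
    reads: list[Read] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate read id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            reads.append(Read(id=rec.id, sequence=seq, description=desc))
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    return ReadSet(label=label, reads=reads)


def write_fasta(rs: ReadSet, path: str | os.PathLike, width: int = 80) -> None:
    """Write a ReadSet as FASTA; round-trips exactly through :func:`read_fasta`.

    ``width <= 0`` writes unwrapped single-line sequences.
    """
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in rs.reads
    ]
    with open(path, "w") as fh:
        if width and width > 0:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        else:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(records)


def filter_min_length(rs: ReadSet, min_len: int = MIN_READ_LENGTH) -> ReadSet:
    """Return a new ReadSet keeping reads of length >= ``min_len``.

    Reads strictly shorter than the threshold are discarded (the
    conventional "less than 60 bp" pre-filter); order is preserved and the
    input is untouched.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return ReadSet(label=rs.label, reads=[r for r in rs.reads if len(r) >= min_len])
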