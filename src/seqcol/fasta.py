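"""FASTA ingestion: turn reference FASTA files into digested collections.

Records stream one at a time (never holding more than one record's
residues), handle gzip transparently, and tolerate CRLF line endings and
blank lines. Sequence names default to the first whitespace-delimited
header token — the near-universal aligner convention — with the full
header retained as non-identity metadata.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .digest import prefixed_identifier, sequence_digest
from .model import DigestedSeqcol, SeqcolSchema, SequenceRecord, build_canonical, encode

__all__ = [
    "FastaEntry",
    "FastaFormatError",
    "read_fasta",
    "parse_fasta",
    "digest_fasta",
    "digest_fasta_entries",
]

# Always-invalid residue characters; catches protein stops and qual mixups.
_FORBIDDEN = re.compile(r"[*0-9]")
# IUPAC nucleotide codes plus gap characters, either case (strict mode).
_IUPAC = re.compile(r"^[ACGTURYSWKMBDHVNacgturyswkmbdhvn.\-]*$")


class FastaFormatError(ValueError):
    """Malformed FASTA content."""


@dataclass(frozen=True)
class FastaEntry:
    """One FASTA record: full header line, short name, concatenated residues."""

    header: str
    name: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


def _open_text(path: str | Path) -> IO[str]:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def parse_fasta(
    handle: Iterable[str],
    strict: bool = False,
    name_policy: str = "first-token",
) -> Iterator[FastaEntry]:
    """Stream :class:`FastaEntry` records from an open text handle.

    ``name_policy`` is either ``"first-token"`` (default) or
    ``"full-header"``. With ``strict=True``, residues outside the IUPAC
    nucleotide alphabet (plus gap characters) are rejected; ``*`` and
    digits are rejected even in lax mode.
    """
    if name_policy not in ("first-token", "full-header"):
        raise ValueError(f"unknown name policy: {name_policy!r}")
    lines = iter(handle)
    first = None
    for line in lines:
        if line.strip():
            first = line
            break
    if first is None:
        raise FastaFormatError("empty FASTA file")
    if not first.lstrip().startswith(">"):
        raise FastaFormatError("content before first '>' header")

    def _chain() -> Iterator[str]:
        yield first
        yield from lines

    for header, residues in SimpleFastaParser(_chain()):
        header = header.strip()
        name = header.split()[0] if name_policy == "first-token" else header
        if not name:
            raise FastaFormatError("record with empty name")
        if _FORBIDDEN.search(residues):
            raise FastaFormatError(
                f"record {name!r} contains '*' or digit characters"
            )
        if strict and not _IUPAC.match(residues):
            raise FastaFormatError(
                f"record {name!r} contains non-IUPAC residue characters"
            )
        yield FastaEntry(header=header, name=name, residues=residues)


def read_fasta(
    path: str | Path,
    strict: bool = False,
    name_policy: str = "first-token",
) -> Iterator[FastaEntry]:
    """Stream records from a plain or gzip-compressed FASTA file."""
    handle = _open_text(path)
    try:
        yield from parse_fasta(handle, strict=strict, name_policy=name_policy)
    finally:
        handle.close()


def digest_fasta_entries(
    entries: Iterable[FastaEntry],
    schema: SeqcolSchema | None = None,
    seq_prefix: str | None = "SQ",
) -> DigestedSeqcol:
    """Encode already-parsed FASTA entries into a digested collection."""
    records = []
    for entry in entries:
        d = sequence_digest(entry.residues)
        if seq_prefix is not None:
            d = prefixed_identifier(d, seq_prefix)
        records.append(
            SequenceRecord(name=entry.name, length=entry.length, sequence_digest=d)
        )
    if not records:
        raise FastaFormatError("no records to encode")
    return encode(build_canonical(records), schema)


def digest_fasta(
    path: str | Path,
    schema: SeqcolSchema | None = None,
    seq_prefix: str | None = "SQ",
    strict: bool = False,
    name_policy: str = "first-token",
) -> DigestedSeqcol:
    """Ingest a FASTA file and run the encoding algorithm.

    Each record contributes its name, residue count (all residue
    characters, including N and ambiguity codes), and the prefixed
    digest of its uppercased residues. ``seq_prefix=None`` emits bare
    digests; the choice changes the collection digest and is surfaced on
    the CLI as ``--no-seq-prefix``.
    """
    result = digest_fasta_entries(
        read_fasta(path, strict=strict, name_policy=name_policy),
        schema=schema,
        seq_prefix=seq_prefix,
    )
    result.metadata["source"] = str(path)
    return result
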