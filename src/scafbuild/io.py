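"""FASTA reading and writing for scaffold construction.

Reading produces a :class:`SequenceIndex` keyed by the first
whitespace-delimited token of each header line (the convention plan
files use to reference records). Record splitting is delegated to
Biopython's ``SimpleFastaParser``; the semantics layered on top —
identifier extraction, duplicate rejection, whitespace stripping within
sequence bodies, and character validation — are this module's.
Writing is bit-exact: ``>`` + header, then the sequence wrapped to a
fixed width, LF newlines, trailing newline.
"""

from __future__ import annotations

import io as _io
from typing import Iterator, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from scafbuild.model import ScaffoldError
from scafbuild.sequence import IUPAC_ALPHABET


class SequenceIndex:
    """Insertion-ordered lookup from record identifier to nucleotide string.

    Supports ``id in index``, ``index[id]`` (the sequence string),
    ``len``, and iteration over identifiers; ``header(id)`` returns the
    full header line the record was read with ('>' excluded).
    """

    def __init__(self) -> None:
        self._records: dict[str, tuple[str, str]] = {}

    def add(self, header: str, seq: str) -> None:
        ident = header.split()[0] if header.split() else ""
        if not ident:
            raise ScaffoldError(
                "malformed-document", "FASTA header with an empty identifier"
            )
        if ident in self._records:
            raise ScaffoldError(
                "duplicate-fasta-id", f"duplicate FASTA identifier {ident!r}"
            )
        self._records[ident] = (header, seq)

    def __contains__(self, ident: str) -> bool:
        return ident in self._records

    def __getitem__(self, ident: str) -> str:
        return self._records[ident][1]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def header(self, ident: str) -> str:
        return self._records[ident][0]

    @classmethod
    def from_dict(cls, records: dict[str, str]) -> "SequenceIndex":
        """Build an index directly from ``{identifier: sequence}`` (tests, API use)."""
        idx = cls()
        for ident, seq in records.items():
            idx.add(ident, seq)
        return idx


def read_fasta_index(stream: Union[str, TextIO]) -> SequenceIndex:
    """Read multi-record FASTA text into a :class:`SequenceIndex`.

    Accepts a text stream or a string. All whitespace inside sequence
    bodies is stripped (so line wrapping and stray internal spaces never
    matter); blank lines are tolerated; LF and CRLF both work. Empty
    sequences are allowed here — a plan referencing one fails validation
    downstream. Non-FASTA content before the first '>' is
    ``malformed-document``; repeated identifiers are
    ``duplicate-fasta-id``; characters outside the IUPAC alphabet are
    ``invalid-character`` with record id and position.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    text = stream.read()
    for line in text.splitlines():
        if line.strip():
            if not line.startswith(">"):
                raise ScaffoldError(
                    "malformed-document",
                    "content before the first '>' header is not FASTA",
                )
            break
    index = SequenceIndex()
    try:
        records = list(SimpleFastaParser(_io.StringIO(text)))
    except ValueError as exc:
        raise ScaffoldError("malformed-document", f"not valid FASTA: {exc}") from exc
    for header, seq in records:
        seq = "".join(seq.split())
        ident = header.split()[0] if header.split() else ""
        for pos, ch in enumerate(seq, 1):
            if ch not in IUPAC_ALPHABET:
                raise ScaffoldError(
                    "invalid-character",
                    f"record {ident or '<unnamed>'!r}: character {ch!r} at "
                    f"position {pos} is not an IUPAC nucleotide code",
                )
        index.add(header, seq)
    return index


def write_fasta(header: str, seq: str, wrap: int = 70, *, stream: TextIO) -> None:
    """Write one FASTA record with the sequence wrapped to ``wrap`` columns.

    The header must be non-empty and newline-free; ``wrap`` >= 1. An
    empty sequence writes the header line only. Output uses LF newlines
    and always ends with a newline.
    """
    if not header or "\n" in header or "\r" in header:
        raise ValueError("header must be non-empty and contain no newline")
    if wrap < 1:
        raise ValueError(f"wrap must be >= 1, got {wrap}")
    stream.write(f">{header}\n")
    for i in range(0, len(seq), wrap):
        stream.write(seq[i : i + wrap] + "\n")
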