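"""Protein FASTA input/output.

Sequences are plain (unaligned) protein strings over the 20 canonical amino
acids plus the ambiguity letters X, B, Z and U that routinely appear in BLAST
dumps.  Gap characters are rejected here: gapped strings exist only inside
:class:`~orthoswap.alignment.LocalAlignment`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, List, TextIO, Union

from Bio import SeqIO as _BioSeqIO

from .errors import SequenceFormatError

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_RESIDUES = "XBZU"
ALLOWED_RESIDUES = frozenset(CANONICAL_RESIDUES + AMBIGUITY_RESIDUES)

PathOrStream = Union[str, os.PathLike, TextIO]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header and is
    the join key everywhere downstream; ``description`` is the (possibly
    empty) remainder of the header.
    """

    id: str
    residues: str
    description: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceFormatError(
                f"record id must be a non-empty whitespace-free token, got {self.id!r}"
            )
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r} has an empty sequence")
        for pos, char in enumerate(self.residues, start=1):
            if char not in ALLOWED_RESIDUES:
                raise SequenceFormatError(
                    f"record {self.id!r}: invalid residue {char!r} at position {pos} "
                    f"(allowed: {CANONICAL_RESIDUES + AMBIGUITY_RESIDUES})"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise SequenceFormatError(
                f"position {position} outside sequence {self.id!r} of length {len(self)}"
            )
        return self.residues[position - 1]


def normalize_residues(raw: str) -> str:
    """Uppercase, drop '*' stop symbols and any whitespace."""
    return "".join(raw.split()).upper().replace("*", "")


def _as_text_handle(source: PathOrStream, mode: str):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


def read_fasta(source: PathOrStream) -> List[SequenceRecord]:
    """Read a protein multi-FASTA into an ordered list of records.

    File order is preserved (it is the tie-break for homolog ranking).
    Lowercase residues are uppercased and ``*`` stop symbols removed; ids must
    be unique; residues must stay within the canonical+ambiguity alphabet.
    """
    handle, close = _as_text_handle(source, "r")
    try:
        records: List[SequenceRecord] = []
        seen = set()
        for bio in _BioSeqIO.parse(handle, "fasta"):
            if bio.id in seen:
                raise SequenceFormatError(f"duplicate sequence id {bio.id!r}")
            seen.add(bio.id)
            desc = bio.description
            if desc == bio.id:
                desc = ""
            elif desc.startswith(bio.id):
                desc = desc[len(bio.id):].strip()
            residues = normalize_residues(str(bio.seq))
            if "-" in str(bio.seq):
                raise SequenceFormatError(
                    f"record {bio.id!r} contains gap characters; aligned FASTA is not accepted"
                )
            if not residues:
                raise SequenceFormatError(f"record {bio.id!r} has an empty sequence")
            records.append(SequenceRecord(id=bio.id, residues=residues, description=desc))
        if not records:
            raise SequenceFormatError("no sequences found in FASTA input")
        return records
    finally:
        if close:
            handle.close()


def read_fasta_str(text: str) -> List[SequenceRecord]:
    """Convenience wrapper: parse FASTA from an in-memory string."""
    return read_fasta(io.StringIO(text))


def write_fasta(
    records: Iterable[SequenceRecord],
    target: PathOrStream,
    line_width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width``.

    The output round-trips exactly through :func:`read_fasta`.
    """
    if line_width < 1:
        raise SequenceFormatError(f"line_width must be >= 1, got {line_width}")
    handle, close = _as_text_handle(target, "w")
    try:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for start in range(0, len(rec.residues), line_width):
                handle.write(rec.residues[start:start + line_width] + "\n")
    finally:
        if close:
            handle.close()


def format_fasta(records: Iterable[SequenceRecord], line_width: int = 60) -> str:
    buf = io.StringIO()
    write_fasta(records, buf, line_width=line_width)
    return buf.getvalue()
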