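"""Optimal pairwise local alignment and query-to-homolog position mapping.

The aligner is Smith-Waterman with affine gap penalties (Gotoh recurrences),
delegated to Biopython's C implementation (:class:`Bio.Align.PairwiseAligner`
in local mode).  Defaults mirror EMBOSS Water: BLOSUM62, gap open 10.0, gap
extend 0.5, where a gap of length L costs ``open + (L-1) * extend``.

Percent identity and similarity follow the Water report convention: the
denominator is the number of alignment columns *including* gap columns;
identity counts equal-letter columns, similarity counts columns whose residue
pair scores strictly positively under the substitution matrix.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, TextIO, Tuple

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices as _submat

from .errors import AlignmentError
from .seqio import CANONICAL_RESIDUES, AMBIGUITY_RESIDUES, SequenceRecord

_FULL_ALPHABET = CANONICAL_RESIDUES + AMBIGUITY_RESIDUES


def _pad_alphabet(array: "_submat.Array") -> "_submat.Array":
    """Extend a matrix so every canonical + ambiguity letter has a row/column.

    Missing entries score 0, so letters absent from the source file (e.g. U
    in BLOSUM62) neither reward nor penalize a column.
    """
    alphabet = str(array.alphabet)
    extra = [c for c in _FULL_ALPHABET if c not in alphabet]
    if not extra:
        return array
    new_alphabet = alphabet + "".join(extra)
    padded = _submat.Array(alphabet=new_alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            padded[a, b] = array[a, b]
    return padded


class SubstitutionMatrix:
    """A symmetric residue-pair scoring matrix.

    Wraps a :class:`Bio.Align.substitution_matrices.Array`; entries for letters
    outside the stored alphabet score 0.
    """

    def __init__(self, name: str, array) -> None:
        self.name = name
        mat = np.asarray(array, dtype=float)
        if not np.allclose(mat, mat.T):
            raise AlignmentError(f"substitution matrix {name!r} is not symmetric")
        # canonical letters the source actually defines must self-score > 0;
        # letters added by zero-padding are exempt (they score 0 everywhere)
        for letter in CANONICAL_RESIDUES:
            if letter in str(array.alphabet) and float(array[letter, letter]) <= 0:
                raise AlignmentError(
                    f"matrix {name!r}: diagonal entry for {letter!r} must be positive"
                )
        self.array = _pad_alphabet(array)

    def score(self, a: str, b: str) -> float:
        alphabet = str(self.array.alphabet)
        if a not in alphabet or b not in alphabet:
            return 0.0
        return float(self.array[a, b])

    @classmethod
    @functools.lru_cache(maxsize=None)
    def blosum62(cls) -> "SubstitutionMatrix":
        """The default matrix (identical scores to EMBOSS EBLOSUM62)."""
        return cls("BLOSUM62", _submat.load("BLOSUM62"))

    @classmethod
    def from_file(cls, path) -> "SubstitutionMatrix":
        """Load an NCBI/EMBOSS-format matrix text file."""
        path = Path(path)
        try:
            array = _submat.read(str(path))
        except Exception as exc:  # pragma: no cover - message passthrough
            raise AlignmentError(f"cannot parse matrix file {path}: {exc}") from exc
        return cls(path.stem, array)

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.name!r})"


@dataclass
class AlignParams:
    """Affine-gap alignment parameters (Water-style defaults)."""

    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: SubstitutionMatrix = field(default_factory=SubstitutionMatrix.blosum62)

    def __post_init__(self) -> None:
        if self.gap_extend < 0 or self.gap_open < 0:
            raise AlignmentError("gap penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            raise AlignmentError(
                f"gap_open ({self.gap_open}) must be >= gap_extend ({self.gap_extend})"
            )

    @functools.cached_property
    def aligner(self) -> "_BioAlign.PairwiseAligner":
        aligner = _BioAlign.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix.array
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


@dataclass(frozen=True)
class LocalAlignment:
    """An optimal local alignment of a query against one homolog.

    Coordinates are 1-based inclusive on the ungapped sequences; a score-0
    (empty) alignment has zero-length aligned strings and all coordinates 0.
    """

    query_id: str
    hit_id: str
    aligned_query: str
    aligned_hit: str
    score: float
    query_start: int
    query_end: int
    hit_start: int
    hit_end: int
    identity_pct: float
    similarity_pct: float
    gap_columns: int
    query_length: int
    hit_length: int

    @property
    def is_empty(self) -> bool:
        return len(self.aligned_query) == 0

    @property
    def columns(self) -> int:
        return len(self.aligned_query)


def _column_stats(
    aligned_query: str, aligned_hit: str, matrix: SubstitutionMatrix
) -> Tuple[float, float, int]:
    total = len(aligned_query)
    if total == 0:
        return 0.0, 0.0, 0
    identities = 0
    similar = 0
    gaps = 0
    for qc, hc in zip(aligned_query, aligned_hit):
        if qc == "-" or hc == "-":
            gaps += 1
            continue
        if qc == hc:
            identities += 1
        if matrix.score(qc, hc) > 0:
            similar += 1
    return 100.0 * identities / total, 100.0 * similar / total, gaps


def compute_identity_similarity(
    alignment: LocalAlignment, matrix: Optional[SubstitutionMatrix] = None
) -> Tuple[float, float]:
    """Percent identity and similarity over all columns (gaps included).

    A zero-length alignment yields (0.0, 0.0).
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    ident, sim, _ = _column_stats(alignment.aligned_query, alignment.aligned_hit, matrix)
    return ident, sim


def _empty_alignment(query: SequenceRecord, hit: SequenceRecord) -> LocalAlignment:
    return LocalAlignment(
        query_id=query.id, hit_id=hit.id, aligned_query="", aligned_hit="",
        score=0.0, query_start=0, query_end=0, hit_start=0, hit_end=0,
        identity_pct=0.0, similarity_pct=0.0, gap_columns=0,
        query_length=len(query), hit_length=len(hit),
    )


def smith_waterman(
    query: SequenceRecord, hit: SequenceRecord, params: Optional[AlignParams] = None
) -> LocalAlignment:
    """Optimal affine-gap local alignment of ``query`` against ``hit``.

    Returns an empty alignment (score 0) when no substring pair scores
    positively; that is a valid result, not an error.
    """
    params = params or AlignParams()
    alignments = params.aligner.align(query.residues, hit.residues)
    if alignments.score <= 0:
        return _empty_alignment(query, hit)
    best = alignments[0]  # deterministic first optimal traceback
    aligned_query = str(best[0])
    aligned_hit = str(best[1])
    coords = best.coordinates
    ident, sim, gaps = _column_stats(aligned_query, aligned_hit, params.matrix)
    return LocalAlignment(
        query_id=query.id,
        hit_id=hit.id,
        aligned_query=aligned_query,
        aligned_hit=aligned_hit,
        score=float(alignments.score),
        query_start=int(coords[0, 0]) + 1,
        query_end=int(coords[0, -1]),
        hit_start=int(coords[1, 0]) + 1,
        hit_end=int(coords[1, -1]),
        identity_pct=ident,
        similarity_pct=sim,
        gap_columns=gaps,
        query_length=len(query),
        hit_length=len(hit),
    )


class MappingKind(Enum):
    RESIDUE = "residue"
    GAP = "gap"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class MappedResidue:
    """What a query position corresponds to on the aligned homolog."""

    kind: MappingKind
    residue: Optional[str] = None
    hit_position: Optional[int] = None

    @property
    def is_residue(self) -> bool:
        return self.kind is MappingKind.RESIDUE

    def token(self) -> str:
        """Single display token: the residue letter, '-' (gap) or '.' (outside)."""
        if self.kind is MappingKind.RESIDUE:
            return self.residue or "?"
        return "-" if self.kind is MappingKind.GAP else "."


def map_position(alignment: LocalAlignment, query_pos: int) -> MappedResidue:
    """Map a 1-based query position into homolog coordinates.

    OUTSIDE when the position lies outside the aligned query span; GAP when
    the homolog has a deletion in the homologous column; otherwise the
    homolog residue together with its own 1-based coordinate.
    """
    if not 1 <= query_pos <= alignment.query_length:
        raise AlignmentError(
            f"query position {query_pos} outside sequence of length {alignment.query_length}"
        )
    if alignment.is_empty or not alignment.query_start <= query_pos <= alignment.query_end:
        return MappedResidue(MappingKind.OUTSIDE)
    q_seen = alignment.query_start - 1
    h_seen = alignment.hit_start - 1
    for qc, hc in zip(alignment.aligned_query, alignment.aligned_hit):
        if qc != "-":
            q_seen += 1
        if hc != "-":
            h_seen += 1
        if qc != "-" and q_seen == query_pos:
            if hc == "-":
                return MappedResidue(MappingKind.GAP)
            return MappedResidue(MappingKind.RESIDUE, residue=hc, hit_position=h_seen)
    raise AssertionError("unreachable: position inside span not found in columns")


ALIGNMENT_TSV_HEADER = (
    "query_id\thit_id\tscore\tidentity_pct\tsimilarity_pct\t"
    "query_start\tquery_end\thit_start\thit_end"
)


def alignment_tsv_row(alignment: LocalAlignment) -> str:
    """One-line TSV summary of an alignment."""
    return "\t".join([
        alignment.query_id,
        alignment.hit_id,
        f"{alignment.score:g}",
        f"{alignment.identity_pct:.1f}",
        f"{alignment.similarity_pct:.1f}",
        str(alignment.query_start),
        str(alignment.query_end),
        str(alignment.hit_start),
        str(alignment.hit_end),
    ])


def write_alignment_fasta(alignment: LocalAlignment, handle: TextIO) -> None:
    """Export the aligned pair as gapped FASTA (internal representation)."""
    for name, seq, start, end in (
        (alignment.query_id, alignment.aligned_query, alignment.query_start, alignment.query_end),
        (alignment.hit_id, alignment.aligned_hit, alignment.hit_start, alignment.hit_end),
    ):
        handle.write(f">{name}/{start}-{end}\n")
        for i in range(0, len(seq), 60):
            handle.write(seq[i:i + 60] + "\n")
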