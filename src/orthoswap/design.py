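"""The replacement engine: rank orthologs, search clusters, build the variant.

Given a query protein, a database of extant homologs and a set of target
positions (grouped into structurally coupled clusters), the engine finds, for
each cluster, the most closely related homolog that carries an acceptable
non-target residue at *every* clustered position simultaneously, and applies
the donor's residues as point substitutions.  Coupling matters: a homolog
that replaces only one of three contacting residues is presumed to need the
compensatory changes at the other two, so it never qualifies alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .alignment import (
    AlignParams,
    LocalAlignment,
    MappedResidue,
    map_position,
    smith_waterman,
)
from .errors import DesignError, TargetSpecError
from .seqio import CANONICAL_RESIDUES, SequenceRecord

Cluster = FrozenSet[int]


@dataclass(frozen=True)
class TargetSpec:
    """The residue type to eliminate and its positions, grouped into clusters.

    Every listed 1-based position must carry ``forbidden_residue`` in the
    query; clusters must be pairwise disjoint.
    """

    forbidden_residue: str
    clusters: Tuple[Cluster, ...]

    def __post_init__(self) -> None:
        if len(self.forbidden_residue) != 1 or self.forbidden_residue not in CANONICAL_RESIDUES:
            raise TargetSpecError(
                f"forbidden residue must be one canonical letter, got {self.forbidden_residue!r}"
            )
        if not self.clusters:
            raise TargetSpecError("at least one cluster is required")
        seen: set = set()
        for cluster in self.clusters:
            if not cluster:
                raise TargetSpecError("empty cluster in target spec")
            overlap = seen & set(cluster)
            if overlap:
                raise TargetSpecError(
                    f"position(s) {sorted(overlap)} appear in more than one cluster"
                )
            seen |= set(cluster)

    @property
    def positions(self) -> Tuple[int, ...]:
        return tuple(sorted(p for cluster in self.clusters for p in cluster))

    def validate_for(self, query: SequenceRecord) -> None:
        for pos in self.positions:
            if not 1 <= pos <= len(query):
                raise TargetSpecError(
                    f"target position {pos} outside query {query.id!r} of length {len(query)}"
                )
            found = query.residue(pos)
            if found != self.forbidden_residue:
                raise TargetSpecError(
                    f"query {query.id!r} position {pos}: expected "
                    f"{self.forbidden_residue!r}, found {found!r}"
                )


@dataclass(frozen=True)
class RankedHomolog:
    record: SequenceRecord
    alignment: LocalAlignment
    rank: int


@dataclass(frozen=True, order=True)
class Substitution:
    """One point mutation, e.g. C140M = (140, 'C', 'M')."""

    position: int
    from_residue: str
    to_residue: str
    hit_coordinate: Optional[int] = field(default=None, compare=False)
    override: bool = field(default=False, compare=False)

    def notation(self) -> str:
        return f"{self.from_residue}{self.position}{self.to_residue}"


@dataclass(frozen=True)
class ReplacementSuggestion:
    """Per-cluster substitutions sourced from a single donor homolog."""

    cluster: Cluster
    source_id: str
    source_rank: int
    source_identity_pct: float
    source_similarity_pct: float
    substitutions: Tuple[Substitution, ...]


@dataclass(frozen=True)
class ClusterResult:
    cluster: Cluster
    suggestion: Optional[ReplacementSuggestion]
    substitutions: Tuple[Substitution, ...]
    resolved: bool


@dataclass(frozen=True)
class DesignResult:
    """Outcome of a full design run, possibly with unresolved clusters."""

    query_id: str
    params: AlignParams
    target: TargetSpec
    clusters: Tuple[ClusterResult, ...]
    variant: SequenceRecord

    @property
    def complete(self) -> bool:
        return all(c.resolved for c in self.clusters)

    @property
    def substitutions(self) -> Tuple[Substitution, ...]:
        return tuple(sorted(s for c in self.clusters for s in c.substitutions))

    @property
    def unresolved_clusters(self) -> Tuple[Cluster, ...]:
        return tuple(c.cluster for c in self.clusters if not c.resolved)


def rank_homologs(
    query: SequenceRecord,
    database: Sequence[SequenceRecord],
    params: Optional[AlignParams] = None,
) -> List[RankedHomolog]:
    """Align every database record to the query and rank by percent identity.

    The sort is stable: ties (and empty, score-0 alignments, which carry
    identity 0) keep database input order.
    """
    if not database:
        raise DesignError("homolog database is empty")
    params = params or AlignParams()
    alignments = [smith_waterman(query, rec, params) for rec in database]
    order = sorted(range(len(database)), key=lambda i: -alignments[i].identity_pct)
    return [
        RankedHomolog(record=database[i], alignment=alignments[i], rank=rank)
        for rank, i in enumerate(order, start=1)
    ]


def _acceptable(mapped: MappedResidue, forbidden_residue: str) -> bool:
    # A usable donor residue must be an aligned canonical letter different
    # from the residue being eliminated; gaps, unaligned positions and
    # ambiguity letters cannot be written as a point mutation.
    return (
        mapped.is_residue
        and mapped.residue in CANONICAL_RESIDUES
        and mapped.residue != forbidden_residue
    )


def find_cluster_replacement(
    ranked: Sequence[RankedHomolog],
    cluster: Iterable[int],
    forbidden_residue: str,
) -> Optional[ReplacementSuggestion]:
    """First (highest-identity) homolog with acceptable residues at *all*
    cluster positions, or None when no homolog qualifies."""
    cluster = frozenset(cluster)
    for hom in ranked:
        substitutions = []
        for pos in sorted(cluster):
            mapped = map_position(hom.alignment, pos)
            if not _acceptable(mapped, forbidden_residue):
                break
            substitutions.append(
                Substitution(
                    position=pos,
                    from_residue=forbidden_residue,
                    to_residue=mapped.residue,
                    hit_coordinate=mapped.hit_position,
                )
            )
        else:
            return ReplacementSuggestion(
                cluster=cluster,
                source_id=hom.record.id,
                source_rank=hom.rank,
                source_identity_pct=hom.alignment.identity_pct,
                source_similarity_pct=hom.alignment.similarity_pct,
                substitutions=tuple(substitutions),
            )
    return None


def apply_substitutions(
    query: SequenceRecord, substitutions: Iterable[Substitution]
) -> SequenceRecord:
    """Apply point mutations to the query, returning a suffixed variant record."""
    subs = sorted(substitutions)
    positions = [s.position for s in subs]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise DesignError(f"duplicate substitution position(s) {dupes}")
    residues = list(query.residues)
    for sub in subs:
        if not 1 <= sub.position <= len(residues):
            raise DesignError(
                f"substitution position {sub.position} outside query of length {len(residues)}"
            )
        found = residues[sub.position - 1]
        if found != sub.from_residue:
            raise DesignError(
                f"position {sub.position}: expected {sub.from_residue!r}, found {found!r}"
            )
        residues[sub.position - 1] = sub.to_residue
    description = "variant"
    if subs:
        description += ": " + ",".join(s.notation() for s in subs)
    return SequenceRecord(
        id=f"{query.id}_variant", residues="".join(residues), description=description
    )


def _validated_overrides(
    overrides: Optional[Mapping[int, str]], target: TargetSpec
) -> Dict[int, str]:
    if not overrides:
        return {}
    valid: Dict[int, str] = {}
    targets = set(target.positions)
    for pos, res in overrides.items():
        if pos not in targets:
            raise TargetSpecError(f"override position {pos} is not a target position")
        if len(res) != 1 or res not in CANONICAL_RESIDUES:
            raise TargetSpecError(
                f"override residue for position {pos} must be canonical, got {res!r}"
            )
        if res == target.forbidden_residue:
            raise TargetSpecError(
                f"override at position {pos} reintroduces forbidden residue {res!r}"
            )
        valid[pos] = res
    return valid


def design_variant(
    query: SequenceRecord,
    database: Sequence[SequenceRecord],
    target: TargetSpec,
    params: Optional[AlignParams] = None,
    overrides: Optional[Mapping[int, str]] = None,
) -> DesignResult:
    """Full design: rank once, resolve each cluster independently, mutate.

    Clusters without a qualifying donor are reported unresolved and their
    positions left unchanged (unless individually overridden by the user);
    the result as a whole is then flagged incomplete rather than aborted.
    """
    params = params or AlignParams()
    target.validate_for(query)
    forced = _validated_overrides(overrides, target)
    ranked = rank_homologs(query, database, params)

    cluster_results: List[ClusterResult] = []
    all_subs: List[Substitution] = []
    for cluster in target.clusters:
        suggestion = find_cluster_replacement(ranked, cluster, target.forbidden_residue)
        subs: Dict[int, Substitution] = (
            {s.position: s for s in suggestion.substitutions} if suggestion else {}
        )
        for pos in cluster:
            if pos in forced:
                subs[pos] = Substitution(
                    position=pos,
                    from_residue=target.forbidden_residue,
                    to_residue=forced[pos],
                    override=True,
                )
        resolved = set(subs) == set(cluster)
        chosen = tuple(sorted(subs.values()))
        cluster_results.append(
            ClusterResult(
                cluster=frozenset(cluster),
                suggestion=suggestion,
                substitutions=chosen,
                resolved=resolved,
            )
        )
        all_subs.extend(chosen)

    variant = apply_substitutions(query, all_subs)
    return DesignResult(
        query_id=query.id,
        params=params,
        target=target,
        clusters=tuple(cluster_results),
        variant=variant,
    )


@dataclass(frozen=True)
class ProfileRow:
    rank: int
    source_id: str
    identity_pct: float
    mapped: Mapping[int, MappedResidue]


@dataclass(frozen=True)
class VariationProfile:
    """Per-position residues observed across the identity-ranked homologs."""

    positions: Tuple[int, ...]
    rows: Tuple[ProfileRow, ...]

    def tally(self, position: int) -> Counter:
        """Residue frequency at one position (GAP/OUTSIDE tallied as tokens)."""
        if position not in self.positions:
            raise DesignError(f"position {position} not in profile")
        counts: Counter = Counter()
        for row in self.rows:
            mapped = row.mapped[position]
            counts[mapped.residue if mapped.is_residue else mapped.kind.name] += 1
        return counts

    def is_conserved(self, position: int, residue: str) -> bool:
        """True when every ranked homolog shows ``residue`` at ``position``."""
        tally = self.tally(position)
        return set(tally) == {residue}


def variation_profile(
    ranked: Sequence[RankedHomolog],
    positions: Iterable[int],
    top_n: Optional[int] = None,
) -> VariationProfile:
    """Mapped residue at each requested position for the top-n homologs."""
    positions = tuple(sorted(set(positions)))
    if not positions:
        raise DesignError("no positions requested")
    if top_n is None:
        top_n = len(ranked)
    if top_n < 1:
        raise DesignError(f"top_n must be >= 1, got {top_n}")
    rows = tuple(
        ProfileRow(
            rank=hom.rank,
            source_id=hom.record.id,
            identity_pct=hom.alignment.identity_pct,
            mapped={pos: map_position(hom.alignment, pos) for pos in positions},
        )
        for hom in ranked[:top_n]
    )
    return VariationProfile(positions=positions, rows=rows)
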