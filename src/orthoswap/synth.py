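"""Synthetic ortholog families with controlled identity and planted residues.

This generator produces databases that statistically resemble a family of
extant orthologs: a homolog at target identity t keeps exactly
``round(t * L)`` of the query's L positions, and every mutated position draws
its new residue from the 19 alternatives weighted by ``exp(BLOSUM62 score)``
against the original, so substitutions are conservative and percent
similarity exceeds percent identity, as in real ortholog alignments.
Chosen residues can be planted at chosen positions to create known donor
homologs, which makes the whole replacement pipeline testable without any
sequence download.

It is a fixture generator, not an evolution simulator: positions mutate
independently (no phylogenetic tree, no site-rate heterogeneity) and indels
(off by default) are short and uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import SubstitutionMatrix
from .errors import SynthesisError
from .seqio import CANONICAL_RESIDUES, SequenceRecord

_CANONICAL = tuple(CANONICAL_RESIDUES)


def _child_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence(entropy=[int(seed), int(index)]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def random_protein(
    length: int,
    seed: int,
    record_id: str = "query",
    exclude: str = "",
) -> SequenceRecord:
    """Uniform-random canonical protein sequence (optionally excluding letters)."""
    if length < 1:
        raise SynthesisError(f"length must be >= 1, got {length}")
    alphabet = [c for c in _CANONICAL if c not in set(exclude)]
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(alphabet, size=length))
    return SequenceRecord(
        id=record_id, residues=residues, description=f"synthetic seed={seed}"
    )


@dataclass(frozen=True)
class HomologPlan:
    """Recipe for one synthetic homolog."""

    id: str
    target_identity: float
    planted: Tuple[Tuple[int, str], ...] = ()
    indel_rate: float = 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic database: one plan per homolog, one master seed."""

    seed: int
    query: SequenceRecord
    plans: Tuple[HomologPlan, ...]

    def __post_init__(self) -> None:
        if not self.plans:
            raise SynthesisError("no homolog plans given")
        ids = [p.id for p in self.plans]
        if len(set(ids)) != len(ids):
            raise SynthesisError("homolog plan ids must be unique")


@dataclass(frozen=True)
class HomologTruth:
    """Ground truth for one generated homolog, for test assertions."""

    id: str
    seed: int
    target_identity: float
    realized_identity: float  # fraction of original query positions unchanged
    planted_map: Tuple[Tuple[int, int, str], ...]  # (query pos, homolog pos, residue)


def _validate_planted(
    planted: Sequence[Tuple[int, str]], length: int
) -> List[Tuple[int, str]]:
    seen = set()
    out = []
    for pos, res in planted:
        if not 1 <= pos <= length:
            raise SynthesisError(f"planted position {pos} outside query of length {length}")
        if res not in CANONICAL_RESIDUES:
            raise SynthesisError(f"planted residue {res!r} at {pos} is not canonical")
        if pos in seen:
            raise SynthesisError(f"planted position {pos} listed twice")
        seen.add(pos)
        out.append((pos, res))
    return out


def _mutate(
    rng: np.random.Generator, original: str, matrix: SubstitutionMatrix
) -> str:
    alternatives = [c for c in _CANONICAL if c != original]
    weights = np.array([np.exp(matrix.score(original, c)) for c in alternatives])
    return str(rng.choice(alternatives, p=weights / weights.sum()))


def generate_homolog(
    query: SequenceRecord,
    target_identity: float,
    planted: Sequence[Tuple[int, str]] = (),
    indel_rate: float = 0.0,
    seed: int = 0,
    record_id: Optional[str] = None,
    matrix: Optional[SubstitutionMatrix] = None,
) -> Tuple[SequenceRecord, HomologTruth]:
    """One synthetic homolog plus its ground truth.

    Exactly ``round((1 - target_identity) * L)`` query positions change
    (planted residues that differ from the query count toward that budget);
    then, when ``indel_rate`` > 0, short (1-3 residue) insertions/deletions
    are applied, never touching planted positions.  Deterministic in ``seed``.
    """
    if not 0 < target_identity <= 1:
        raise SynthesisError(f"target_identity must be in (0, 1], got {target_identity}")
    if not 0 <= indel_rate < 1:
        raise SynthesisError(f"indel_rate must be in [0, 1), got {indel_rate}")
    matrix = matrix or SubstitutionMatrix.blosum62()
    length = len(query)
    planted = _validate_planted(planted, length)
    n_diff = round(length * (1.0 - target_identity))
    planted_diff = sum(1 for pos, res in planted if query.residue(pos) != res)
    if planted_diff > n_diff:
        raise SynthesisError(
            f"target_identity {target_identity} allows {n_diff} differences but "
            f"{planted_diff} planted residues already differ from the query"
        )

    rng = np.random.default_rng(seed)
    planted_positions = {pos for pos, _ in planted}
    pool = np.array([p for p in range(1, length + 1) if p not in planted_positions])
    n_random = n_diff - planted_diff
    if n_random > len(pool):
        raise SynthesisError(
            f"cannot place {n_random} random substitutions among {len(pool)} free positions"
        )
    chosen = rng.choice(pool, size=n_random, replace=False) if n_random else np.array([], int)

    residues = list(query.residues)
    for pos in sorted(int(p) for p in chosen):
        residues[pos - 1] = _mutate(rng, residues[pos - 1], matrix)
    for pos, res in planted:
        residues[pos - 1] = res

    # indels: per original position, right-to-left so indices stay valid
    labels: List[Optional[int]] = list(range(1, length + 1))
    if indel_rate > 0:
        for pos in range(length, 0, -1):
            if rng.random() >= indel_rate:
                continue
            ins_len = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion before pos
                idx = pos - 1
                inserted = [str(rng.choice(_CANONICAL)) for _ in range(ins_len)]
                residues[idx:idx] = inserted
                labels[idx:idx] = [None] * ins_len
            else:  # deletion of up to len current residues from pos, sparing planted sites
                if pos not in labels:
                    continue  # already removed by an earlier (higher-position) deletion
                idx = labels.index(pos)
                end = min(idx + ins_len, len(labels))
                if any(lbl in planted_positions for lbl in labels[idx:end] if lbl is not None):
                    continue
                del residues[idx:end]
                del labels[idx:end]

    planted_map = tuple(
        (pos, labels.index(pos) + 1, res) for pos, res in planted
    )
    rec_id = record_id or f"{query.id}_synth{seed}"
    record = SequenceRecord(
        id=rec_id,
        residues="".join(residues),
        description=f"synthetic homolog seed={seed} target_identity={target_identity:.3f}",
    )
    truth = HomologTruth(
        id=rec_id,
        seed=seed,
        target_identity=target_identity,
        realized_identity=(length - n_diff) / length,
        planted_map=planted_map,
    )
    return record, truth


def generate_database(
    spec: SyntheticSpec, matrix: Optional[SubstitutionMatrix] = None
) -> Tuple[List[SequenceRecord], Dict[str, HomologTruth]]:
    """All homologs of a spec, in plan order, with a ground-truth manifest."""
    records: List[SequenceRecord] = []
    manifest: Dict[str, HomologTruth] = {}
    for index, plan in enumerate(spec.plans):
        record, truth = generate_homolog(
            spec.query,
            plan.target_identity,
            planted=plan.planted,
            indel_rate=plan.indel_rate,
            seed=_child_seed(spec.seed, index),
            record_id=plan.id,
            matrix=matrix,
        )
        records.append(record)
        manifest[plan.id] = truth
    return records, manifest


# --------------------------------------------------------------------------
# Study conditions: a chaperonin-like family with coupled cysteine clusters
# --------------------------------------------------------------------------

CYSTEINE_POSITIONS = (140, 237, 286, 359, 393, 470, 484)
EQUATORIAL_CLUSTER = frozenset({140, 470, 484})
APICAL_CLUSTER = frozenset({237, 286})
STUDY_CLUSTERS = (
    EQUATORIAL_CLUSTER,
    APICAL_CLUSTER,
    frozenset({359}),
    frozenset({393}),
)
STUDY_QUERY_LENGTH = 543


def _plant(replacements: Dict[int, str]) -> Tuple[Tuple[int, str], ...]:
    # every target position is pinned: C unless explicitly replaced
    return tuple(
        (pos, replacements.get(pos, "C")) for pos in CYSTEINE_POSITIONS
    )


@dataclass(frozen=True)
class StudyFamily:
    """A synthetic archaeal-chaperonin-like ortholog family.

    543-residue query with cysteines at exactly the seven positions
    140/237/286/359/393/470/484 (clusters: equatorial 140+470+484, apical
    237+286, singletons 359 and 393), plus a database in which the expected
    donor for every cluster is known by construction.
    """

    query: SequenceRecord
    database: List[SequenceRecord]
    manifest: Dict[str, HomologTruth]
    clusters: Tuple[frozenset, ...]
    expected_donors: Dict[frozenset, Tuple[str, Dict[int, str]]]


def example_cysteine_family(seed: int) -> StudyFamily:
    """Generate the standard study family for a given seed.

    Donor identities follow the identities of the extant donors in the
    original chaperonin design (85.8 / 66.3 / 59.2 percent); the Cys-393
    donor sits at 88 percent ("closely related").  Decoys above each donor
    keep cysteine at the relevant positions, including a 90-percent decoy
    with a replacement at only one of the three coupled equatorial positions,
    so cluster coupling forces the 85.8-percent donor.
    """
    query_core = random_protein(
        STUDY_QUERY_LENGTH, seed=_child_seed(seed, 1000), record_id="query_cpn",
        exclude="C",
    )
    residues = list(query_core.residues)
    for pos in CYSTEINE_POSITIONS:
        residues[pos - 1] = "C"
    query = SequenceRecord(
        id="query_cpn",
        residues="".join(residues),
        description=f"synthetic chaperonin-like query seed={seed}",
    )

    plans = (
        HomologPlan("ortho_near_a", 0.95, _plant({})),
        HomologPlan("ortho_near_b", 0.92, _plant({})),
        HomologPlan("ortho_eq_partial", 0.90, _plant({140: "L"})),
        HomologPlan("ortho_393", 0.88, _plant({393: "S"})),
        HomologPlan("ortho_eq", 0.858, _plant({140: "M", 470: "Y", 484: "T"})),
        HomologPlan("ortho_bg80", 0.80, _plant({})),
        HomologPlan("ortho_ap_partial", 0.75, _plant({237: "E"})),
        HomologPlan("ortho_bg70", 0.70, _plant({})),
        HomologPlan("ortho_ap", 0.663, _plant({237: "E", 286: "V"})),
        HomologPlan("ortho_bg60", 0.60, _plant({})),
        HomologPlan("ortho_359", 0.592, _plant({359: "V"})),
        HomologPlan("ortho_bg45", 0.45, _plant({})),
    )
    spec = SyntheticSpec(seed=seed, query=query, plans=plans)
    database, manifest = generate_database(spec)

    expected = {
        EQUATORIAL_CLUSTER: ("ortho_eq", {140: "M", 470: "Y", 484: "T"}),
        APICAL_CLUSTER: ("ortho_ap", {237: "E", 286: "V"}),
        frozenset({359}): ("ortho_359", {359: "V"}),
        frozenset({393}): ("ortho_393", {393: "S"}),
    }
    return StudyFamily(
        query=query,
        database=database,
        manifest=manifest,
        clusters=STUDY_CLUSTERS,
        expected_donors=expected,
    )
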