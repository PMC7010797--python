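"""Independent oracles used by the test suite (and only by it).

``enumerated_local_score`` explores every local alignment of two peptides —
every start pair, every interleaving of match/gap moves, every stopping
point — top-down with memoization, scoring affine gaps as
open + (L-1) * extend.  It shares no code or formulation with the aligner
under test.  ``tiny_exhaustive_local_score`` is a literal move-string
enumeration (no memoization) used to validate the oracle itself on very
small inputs.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable

ScoreFn = Callable[[str, str], float]


def enumerated_local_score(
    query: str, hit: str, score: ScoreFn, gap_open: float, gap_extend: float
) -> float:
    """Best local alignment score by exhaustive (memoized) enumeration."""

    @lru_cache(maxsize=None)
    def best_from(i: int, j: int, state: int) -> float:
        # state: 0 = last column was a residue pair, 1 = gap in query row
        # (hit residue consumed), 2 = gap in hit row (query residue consumed)
        value = 0.0  # the alignment may stop here
        if i < len(query) and j < len(hit):
            value = max(value, score(query[i], hit[j]) + best_from(i + 1, j + 1, 0))
        if j < len(hit):
            cost = gap_extend if state == 1 else gap_open
            value = max(value, -cost + best_from(i, j + 1, 1))
        if i < len(query):
            cost = gap_extend if state == 2 else gap_open
            value = max(value, -cost + best_from(i + 1, j, 2))
        return value

    best = 0.0
    for i in range(len(query) + 1):
        for j in range(len(hit) + 1):
            best = max(best, best_from(i, j, 0))
    best_from.cache_clear()
    return best


def tiny_exhaustive_local_score(
    query: str, hit: str, score: ScoreFn, gap_open: float, gap_extend: float
) -> float:
    """Literal enumeration of all move strings over all substring pairs.

    Exponential; only for sequences of length <= 4.
    """
    assert len(query) <= 4 and len(hit) <= 4

    def global_scores(a: str, b: str):
        # yield the score of every complete gapped pairing of a vs b
        def walk(i: int, j: int, acc: float, last: str):
            if i == len(a) and j == len(b):
                yield acc
                return
            if i < len(a) and j < len(b):
                yield from walk(i + 1, j + 1, acc + score(a[i], b[j]), "M")
            if j < len(b):
                cost = gap_extend if last == "I" else gap_open
                yield from walk(i, j + 1, acc - cost, "I")
            if i < len(a):
                cost = gap_extend if last == "D" else gap_open
                yield from walk(i + 1, j, acc - cost, "D")

        yield from walk(0, 0, 0.0, "M")

    best = 0.0
    for i0 in range(len(query) + 1):
        for i1 in range(i0, len(query) + 1):
            for j0 in range(len(hit) + 1):
                for j1 in range(j0, len(hit) + 1):
                    sub_q, sub_h = query[i0:i1], hit[j0:j1]
                    if not sub_q and not sub_h:
                        continue
                    best = max(best, max(global_scores(sub_q, sub_h)))
    return best


def brute_force_best_donor(ranked, cluster, forbidden_residue):
    """Independent scan of *all* ranked homologs for cluster qualification.

    Re-derives qualification from map_position and returns the id of the
    maximum-identity qualifying homolog (earliest on ties), or None.
    """
    from orthoswap.alignment import map_position
    from orthoswap.seqio import CANONICAL_RESIDUES

    best_id, best_identity = None, None
    for hom in ranked:
        ok = True
        for pos in cluster:
            mapped = map_position(hom.alignment, pos)
            if not (
                mapped.is_residue
                and mapped.residue in CANONICAL_RESIDUES
                and mapped.residue != forbidden_residue
            ):
                ok = False
                break
        if ok and (best_identity is None or hom.alignment.identity_pct > best_identity):
            best_id, best_identity = hom.record.id, hom.alignment.identity_pct
    return best_id


def brute_force_components(positions, pair_in_contact):
    """Connected components by breadth-first search over an explicit
    pairwise contact predicate."""
    positions = list(positions)
    unvisited = set(positions)
    components = []
    while unvisited:
        seed_pos = min(unvisited)
        stack, component = [seed_pos], set()
        unvisited.discard(seed_pos)
        while stack:
            current = stack.pop()
            component.add(current)
            for other in list(unvisited):
                if pair_in_contact(current, other):
                    unvisited.discard(other)
                    stack.append(other)
        components.append(frozenset(component))
    return sorted(components, key=min)
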