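"""Position clusters from atomic coordinates.

Two residues are in steric contact when the minimum distance over all pairs
of their heavy atoms falls below a cutoff (default 4.5 Å).  Clusters are the
connected components of the contact graph (single linkage), so three residues
at pairwise a-b = 3 Å, b-c = 3 Å, a-c = 100 Å still form one cluster.  The
cutoff is a tool parameter and is always logged in reports; it is not derived
from any published criterion.

Only one chain is analyzed at a time; inter-subunit contacts across an
assembly are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Tuple

import gemmi
import numpy as np

from .errors import StructureError

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, minimum heavy-atom distance


@dataclass(frozen=True)
class ResidueCoordinates:
    """Heavy-atom coordinates per 1-based residue position of one chain."""

    chain_id: str
    coords: Mapping[int, np.ndarray]  # position -> (n_atoms, 3) float array
    missing: Tuple[int, ...] = ()

    def positions(self) -> Tuple[int, ...]:
        return tuple(sorted(self.coords))


def _pick_altloc(atoms: List[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties prefer blank/'A' altloc, then lexicographic
    def key(atom: gemmi.Atom):
        alt = atom.altloc or "A"
        return (-atom.occ, 0 if alt == "A" else 1, alt)

    return sorted(atoms, key=key)[0]


def _chain(structure: gemmi.Structure, chain_id: str) -> gemmi.Chain:
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model)
        raise StructureError(f"chain {chain_id!r} not found (available: {available})")
    return chain


def load_residue_coordinates(
    structure_file,
    chain_id: str,
    positions: Optional[Iterable[int]] = None,
) -> ResidueCoordinates:
    """Heavy-atom coordinates for the requested residues of one chain.

    Residues keep the author numbering of the file.  Hydrogens and waters are
    excluded; alternate conformations are reduced to a single atom (highest
    occupancy, ties broken toward altloc 'A').  Requested residues absent
    from the model are reported in ``missing``, never fabricated.
    """
    try:
        structure = gemmi.read_structure(str(structure_file))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot read structure {structure_file}: {exc}") from exc
    if len(structure) == 0:
        raise StructureError(f"no models in structure {structure_file}")
    chain = _chain(structure, chain_id)
    wanted = set(positions) if positions is not None else None

    coords: Dict[int, np.ndarray] = {}
    for residue in chain:
        if residue.is_water():
            continue
        num = residue.seqid.num
        if wanted is not None and num not in wanted:
            continue
        by_name: Dict[str, List[gemmi.Atom]] = {}
        for atom in residue:
            if atom.element.is_hydrogen:
                continue
            by_name.setdefault(atom.name, []).append(atom)
        points = [
            (a.pos.x, a.pos.y, a.pos.z)
            for a in (_pick_altloc(group) for group in by_name.values())
        ]
        if not points:
            continue
        arr = np.asarray(points, dtype=float)
        if not np.isfinite(arr).all():
            raise StructureError(f"non-finite coordinates in residue {num} of chain {chain_id}")
        coords[num] = arr

    missing: Tuple[int, ...] = ()
    if wanted is not None:
        missing = tuple(sorted(wanted - set(coords)))
        if not coords:
            raise StructureError(
                f"none of the requested positions {sorted(wanted)} present in chain {chain_id!r}"
            )
    if not coords:
        raise StructureError(f"no heavy-atom residues found in chain {chain_id!r}")
    return ResidueCoordinates(chain_id=chain_id, coords=coords, missing=missing)


def residue_positions_of(structure_file, chain_id: str, residue_letter: str) -> Tuple[int, ...]:
    """All positions in the chain whose residue type matches a one-letter code."""
    structure = gemmi.read_structure(str(structure_file))
    chain = _chain(structure, chain_id)
    out = []
    for residue in chain:
        info = gemmi.find_tabulated_residue(residue.name)
        if info is not None and info.one_letter_code.upper() == residue_letter.upper():
            out.append(residue.seqid.num)
    return tuple(sorted(out))


def min_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum Euclidean distance between two heavy-atom point sets."""
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).min())


def contact_clusters(
    coords: ResidueCoordinates,
    positions: Iterable[int],
    cutoff_angstrom: float = DEFAULT_CONTACT_CUTOFF,
) -> List[FrozenSet[int]]:
    """Connected components of the steric-contact graph over ``positions``.

    Output sets are disjoint, cover every input position once, and are sorted
    by their smallest member.
    """
    if cutoff_angstrom <= 0:
        raise StructureError(f"cutoff must be positive, got {cutoff_angstrom}")
    positions = sorted(set(positions))
    if not positions:
        raise StructureError("no positions given")
    for pos in positions:
        if pos not in coords.coords:
            raise StructureError(f"position {pos} has no coordinates in chain {coords.chain_id!r}")

    parent = {p: p for p in positions}

    def find(p: int) -> int:
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, a in enumerate(positions):
        for b in positions[i + 1:]:
            if min_distance(coords.coords[a], coords.coords[b]) < cutoff_angstrom:
                parent[find(a)] = find(b)

    components: Dict[int, set] = {}
    for p in positions:
        components.setdefault(find(p), set()).add(p)
    return sorted((frozenset(c) for c in components.values()), key=min)


def format_clusters(clusters: Iterable[FrozenSet[int]]) -> str:
    """Render clusters in the CLI syntax, e.g. ``"140,470,484;237,286;359"``."""
    return ";".join(",".join(str(p) for p in sorted(c)) for c in clusters)
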