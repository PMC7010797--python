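"""Shared fixtures: matrices, the synthetic study family, a PDB builder."""

from __future__ import annotations

import pytest

from orthoswap.alignment import AlignParams, SubstitutionMatrix
from orthoswap.synth import example_cysteine_family

FAMILY_SEED = 11


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def default_params():
    return AlignParams()


@pytest.fixture(scope="session")
def family():
    """The synthetic chaperonin-like study family (543-aa query, 12 homologs)."""
    return example_cysteine_family(FAMILY_SEED)


def make_pdb(residues) -> str:
    """Build minimal PDB text for chain A.

    ``residues``: list of (resnum, resname, atoms) where each atom is
    (name, element, x, y, z) or (name, element, x, y, z, occupancy, altloc).
    """
    lines = []
    serial = 0
    for resnum, resname, atoms in residues:
        for atom in atoms:
            name, element, x, y, z = atom[:5]
            occ = atom[5] if len(atom) > 5 else 1.0
            alt = atom[6] if len(atom) > 6 else " "
            serial += 1
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{alt:1s}{resname:>3s} A{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def write_pdb(tmp_path):
    def _write(residues, name="model.pdb"):
        path = tmp_path / name
        path.write_text(make_pdb(residues))
        return path

    return _write
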