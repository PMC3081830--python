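"""Shared fixtures: a tiny hand-built glycine PDB and structure helpers."""

from __future__ import annotations

import pytest
from hypothesis import settings

from foldscore.contacts import AtomRecord, Structure, _infer_bonds

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Free glycine (zwitterion-free, idealised coordinates), 5 heavy atoms +
# 5 hydrogens.  Synthetic fixture, not taken from any deposited structure.
GLYCINE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  H1  GLY A   1       0.000   0.000  -1.010  1.00  0.00           H
ATOM      3  CA  GLY A   1       1.470   0.000   0.000  1.00  0.00           C
ATOM      4  HA2 GLY A   1       1.470   1.090   0.000  1.00  0.00           H
ATOM      5  HA3 GLY A   1       1.470  -0.770  -0.770  1.00  0.00           H
ATOM      6  C   GLY A   1       1.980   0.000   1.440  1.00  0.00           C
ATOM      7  O   GLY A   1       3.210   0.000   1.440  1.00  0.00           O
ATOM      8  OXT GLY A   1       1.480   0.000   2.690  1.00  0.00           O
ATOM      9  HXT GLY A   1       1.480   0.960   2.690  1.00  0.00           H
ATOM     10  H2  GLY A   1      -0.340  -0.950   0.000  1.00  0.00           H
END
"""
GLYCINE_N_ATOMS = 10
GLYCINE_N_HEAVY = 5

# Same glycine with the CA atom duplicated as altloc A (occupancy 0.6,
# x=1.470) and altloc B (occupancy 0.4, shifted): the parser must keep
# the higher-occupancy A conformer only.
GLYCINE_ALTLOC_PDB = GLYCINE_PDB.replace(
    "ATOM      3  CA  GLY A   1       1.470   0.000   0.000  1.00  0.00           C",
    "ATOM      3  CA AGLY A   1       1.470   0.000   0.000  0.60  0.00           C\n"
    "ATOM      4  CA BGLY A   1       1.570   0.100   0.000  0.40  0.00           C",
)


@pytest.fixture
def glycine_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLYCINE_PDB)
    return p


def make_structure(atom_specs, structure_id="test"):
    """Build a Structure from (name, element, resname, resi, chain, xyz) tuples.

    Bonds are inferred with the same distance rule as the PDB reader.
    """
    atoms = [
        AtomRecord(
            serial=i + 1,
            name=name,
            element=element,
            residue_name=resname,
            residue_index=resi,
            chain=chain,
            xyz=tuple(float(c) for c in xyz),
        )
        for i, (name, element, resname, resi, chain, xyz) in enumerate(atom_specs)
    ]
    return Structure(structure_id=structure_id, atoms=atoms, bonds=_infer_bonds(atoms))
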