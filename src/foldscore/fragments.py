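"""Extraction of link-atom-capped fragment pairs for external energy engines.

For a detected contact, the two interacting residues are cut out of the
protein; every severed single bond X-Y (X kept) is replaced by an X-H
"link atom" placed on the original X->Y bond vector at the standard X-H
bond length.  The capped pair can be written as PDB or XYZ for evaluation
by quantum-chemical or force-field programs; this package never computes
those energies itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contacts import AtomRecord, InteractionContact, Structure
from .exceptions import FragmentError, ValidationError

__all__ = ["LinkAtom", "CappedFragment", "extract_fragment_pair",
           "write_fragment_pdb", "write_fragment_xyz"]

# standard X-H bond lengths (A) for link-atom placement
_XH_LENGTH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

# below these lengths an X-Y bond has double/aromatic character and must not
# be severed (capping is only defined for single bonds)
_SINGLE_BOND_MIN = {
    frozenset(("C", "O")): 1.32,
    frozenset(("C", "C")): 1.42,
    frozenset(("C", "N")): 1.38,
    frozenset(("N", "O")): 1.25,
}


@dataclass(frozen=True)
class LinkAtom:
    """Hydrogen replacing a severed covalent bond.

    ``kept_serial``/``removed_serial`` identify the bond endpoints in the
    parent structure (the kept atom stays in the fragment).
    """

    xyz: tuple[float, float, float]
    kept_serial: int
    removed_serial: int
    element: str = "H"


@dataclass
class CappedFragment:
    """A connected set of atoms cut from a parent structure, hydrogen-capped."""

    parent_id: str
    atoms: list[AtomRecord]
    link_atoms: list[LinkAtom] = field(default_factory=list)
    net_charge: int = 0

    @property
    def n_atoms(self) -> int:
        return len(self.atoms) + len(self.link_atoms)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]


def _connected(indices: set[int], structure: Structure) -> bool:
    if not indices:
        return False
    seen = set()
    stack = [next(iter(indices))]
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        stack.extend(j for j in structure.neighbors(i) if j in indices and j not in seen)
    return seen == indices


def _cap(structure: Structure, indices: set[int]) -> CappedFragment:
    atoms = structure.atoms
    if not _connected(indices, structure):
        raise FragmentError(
            "selection does not form a connected covalent unit; refusing to "
            "cap a disconnected fragment"
        )
    links: list[LinkAtom] = []
    for i in sorted(indices):
        for j in sorted(structure.neighbors(i)):
            if j in indices:
                continue
            xi = np.array(atoms[i].xyz)
            xj = np.array(atoms[j].xyz)
            d = float(np.linalg.norm(xj - xi))
            pair = frozenset((atoms[i].element, atoms[j].element))
            if pair in _SINGLE_BOND_MIN and d < _SINGLE_BOND_MIN[pair]:
                raise FragmentError(
                    f"bond {atoms[i].name}-{atoms[j].name} ({d:.2f} A) has "
                    "double/aromatic character; only single bonds can be "
                    "capped with a link atom"
                )
            try:
                length = _XH_LENGTH[atoms[i].element]
            except KeyError:
                raise FragmentError(
                    f"no standard X-H bond length for element "
                    f"{atoms[i].element!r}"
                ) from None
            pos = xi + (xj - xi) / d * length
            links.append(
                LinkAtom(
                    xyz=(float(pos[0]), float(pos[1]), float(pos[2])),
                    kept_serial=atoms[i].serial,
                    removed_serial=atoms[j].serial,
                )
            )
    return CappedFragment(
        parent_id=structure.structure_id,
        atoms=[atoms[i] for i in sorted(indices)],
        link_atoms=links,
    )


def _select_residue_atoms(structure: Structure, residue_key) -> set[int]:
    return {
        i for i, a in enumerate(structure.atoms) if a.residue_key == residue_key
    }


def extract_fragment_pair(
    structure: Structure,
    contact: InteractionContact,
    *,
    selection: str = "residue",
) -> tuple[CappedFragment, CappedFragment]:
    """Cut the two residues of a contact out of the structure and cap them.

    The default ``"residue"`` selection takes every atom of each contact
    residue; severed backbone bonds are capped with hydrogens placed along
    the original bond vectors.  The two fragments share no atoms.
    """
    if selection != "residue":
        raise ValidationError(f"unknown selection rule {selection!r}")
    for idx in contact.atoms:
        if not 0 <= idx < len(structure.atoms):
            raise ValidationError("contact does not belong to this structure")
    sel_a = _select_residue_atoms(structure, contact.residue_pair[0])
    sel_b = _select_residue_atoms(structure, contact.residue_pair[1])
    if not sel_a or not sel_b:
        raise FragmentError("contact residues not found in structure")
    return _cap(structure, sel_a), _cap(structure, sel_b)


def _all_atoms(fragment: CappedFragment):
    """Member atoms followed by link atoms, as (name, element, residue info, xyz)."""
    rows = []
    for a in fragment.atoms:
        rows.append((a.name, a.element, a.residue_name, a.residue_index, a.chain, a.xyz))
    for k, la in enumerate(fragment.link_atoms, start=1):
        rows.append((f"HL{k}", la.element, "LNK", 0, "L", la.xyz))
    return rows


def write_fragment_pdb(fragment: CappedFragment, path: str | Path) -> None:
    """Write the capped fragment as a minimal fixed-column PDB file."""
    lines = []
    for serial, (name, element, resname, resi, chain, xyz) in enumerate(
        _all_atoms(fragment), start=1
    ):
        nm = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {nm:<4.4s} {resname:<3.3s} {chain[:1]}"
            f"{resi:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00          {element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fragment_xyz(fragment: CappedFragment, path: str | Path) -> None:
    rows = _all_atoms(fragment)
    lines = [str(len(rows)), f"{fragment.parent_id} capped fragment"]
    for _, element, _, _, _, xyz in rows:
        lines.append(f"{element:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def fragment_filenames(structure_id: str, contact_id: str) -> tuple[str, str]:
    """Conventional output names <structure>_<contact>_{a,b}.pdb."""
    return (
        f"{structure_id}_{contact_id}_a.pdb",
        f"{structure_id}_{contact_id}_b.pdb",
    )
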