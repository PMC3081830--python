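"""Synthetic inputs with known ground truth.

Three generators make every other module testable without external data:

* Gaussian deviation samples emulating a fragment interaction-energy
  database (per-class mean/variance known by construction).
* Toy PDB structures with planted hydrogen-bond motifs and van der Waals
  probe pairs at ideal geometry, spatially isolated so the planted contact
  counts are the exact ground truth for the detectors.
* Decoy collections with a planted energy funnel (true native energy lowest
  by a configurable margin) plus per-contact method errors drawn from a
  planted error table.

Planted motifs are rigid idealised chemical groups (a formamide-like
N-H...O=C pair for hydrogen bonds, methane-like CH probes for van der
Waals contacts), not physical peptides: the point is analytic ground
truth, not realistic conformations.  All randomness flows through an
explicit integer seed; the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .decoys import DECOY, NATIVE, RELAXED, DecoySystem, FoldRecord
from .errormodel import (
    NONPOLAR,
    POLAR,
    ContactCounts,
    DeviationRecord,
    MethodErrorTable,
)
from .exceptions import ValidationError

__all__ = [
    "FixtureManifest",
    "generate_deviation_samples",
    "generate_toy_structure",
    "generate_decoy_collection",
]

#: Range (kcal/mol) from which reference fragment interaction energies are
#: drawn — typical magnitudes for hydrogen bonds and dispersion contacts.
_E_REF_RANGE = (-12.0, -1.0)

_GRID_SPACING = 18.0  # A between planted groups; guarantees >8 A isolation
_NH = 1.01  # N-H bond length, A
_CH = 1.09  # C-H bond length, A
_CO_DOUBLE = 1.23  # C=O bond length, A
_HBOND_NA = 2.9  # planted donor-acceptor N...O distance, A
_VDW_CC = 3.6  # planted probe C...C distance, A (<= 1.7+1.7+0.5)


@dataclass
class FixtureManifest:
    """Ground truth and provenance for one generated fixture.

    Regenerating with the recorded ``arguments`` (which include the seed)
    reproduces byte-identical files.
    """

    kind: str
    seed: int
    arguments: dict
    planted: dict
    files: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        doc = {
            "kind": self.kind,
            "seed": self.seed,
            "arguments": self.arguments,
            "planted": self.planted,
            "files": self.files,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def read(cls, path: str | Path) -> "FixtureManifest":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


# ---------------------------------------------------------------------------
# deviation samples
# ---------------------------------------------------------------------------

def generate_deviation_samples(
    mu: float,
    sigma2: float,
    n: int,
    interaction_class: str = POLAR,
    seed: int = 0,
) -> list[DeviationRecord]:
    """Draw ``n`` fragment deviation records with i.i.d. Gaussian errors.

    Deviations are drawn from N(mu, sigma2); reference energies uniformly
    from [-12, -1] kcal/mol and ``e_approx = e_ref + deviation``.  With
    ``sigma2 == 0`` every deviation is exactly ``mu``.
    """
    if n < 2:
        raise ValidationError("need n >= 2 samples (variance needs two points)")
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    e_ref = rng.uniform(*_E_REF_RANGE, size=n)
    if sigma2 == 0:
        dev = np.full(n, float(mu))
    else:
        dev = rng.normal(mu, math.sqrt(sigma2), size=n)
    return [
        DeviationRecord(
            fragment_id=f"frag{i:06d}",
            interaction_class=interaction_class,
            e_approx=float(e_ref[i] + dev[i]),
            e_ref=float(e_ref[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _pdb_line(serial, name, resname, chain, resi, xyz, element):
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {nm:<4.4s} {resname:<3.3s} {chain}{resi:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
        f"{element:>2.2s}"
    )


def generate_toy_structure(
    n_hbonds: int,
    n_vdw: int,
    seed: int = 0,
    path: str | Path = "toy.pdb",
) -> FixtureManifest:
    """Write a PDB file with exactly the requested planted contacts.

    Each hydrogen-bond motif is a formamide-like pair: an N-H donor residue
    and an O=C acceptor residue with N...O = 2.9 A and a 180 deg
    D-H...A angle.  Each van der Waals motif is a pair of CH probes with
    C...C = 3.6 A.  Groups sit on a 3-D grid with 18 A spacing (randomly
    oriented per group), so no spurious inter-group contact is possible;
    two isolated single-probe padding residues guarantee the file always
    contains atoms (and hydrogens).  Residue indices within each planted
    pair differ by 2, satisfying the sequence-separation rule.
    """
    if n_hbonds < 0 or n_vdw < 0:
        raise ValidationError("planted contact counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_groups = n_hbonds + n_vdw + 2  # +2 isolated padding probes
    m = max(1, math.ceil(n_groups ** (1 / 3)))
    centers = []
    for k in range(n_groups):
        ix, iy, iz = k % m, (k // m) % m, k // (m * m)
        centers.append(np.array([ix, iy, iz], dtype=float) * _GRID_SPACING)
    axes = _unit_vectors(rng, n_groups)

    lines = []
    serial = 0
    resi = 0

    def emit(name, resname, index, xyz, element):
        nonlocal serial
        serial += 1
        lines.append(_pdb_line(serial, name, resname, "A", index, xyz, element))

    g = 0
    for _ in range(n_hbonds):
        c, u = centers[g], axes[g]
        g += 1
        resi += 4
        emit("N", "DON", resi - 3, c, "N")
        emit("H1", "DON", resi - 3, c + u * _NH, "H")
        emit("O", "ACC", resi - 1, c + u * _HBOND_NA, "O")
        emit("C", "ACC", resi - 1, c + u * (_HBOND_NA + _CO_DOUBLE), "C")
    for _ in range(n_vdw):
        c, w = centers[g], axes[g]
        g += 1
        resi += 4
        half = w * (_VDW_CC / 2)
        emit("C", "PRA", resi - 3, c - half, "C")
        emit("H1", "PRA", resi - 3, c - half - w * _CH, "H")
        emit("C", "PRB", resi - 1, c + half, "C")
        emit("H1", "PRB", resi - 1, c + half + w * _CH, "H")
    for _ in range(2):  # padding: lone probes, no partner within reach
        c, w = centers[g], axes[g]
        g += 1
        resi += 4
        emit("C", "PAD", resi - 3, c, "C")
        emit("H1", "PAD", resi - 3, c + w * _CH, "H")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")

    return FixtureManifest(
        kind="toy_structure",
        seed=seed,
        arguments={"n_hbonds": n_hbonds, "n_vdw": n_vdw, "seed": seed},
        planted={POLAR: n_hbonds, NONPOLAR: n_vdw, "n_atoms": serial},
        files=[str(path)],
    )


# ---------------------------------------------------------------------------
# decoy collections
# ---------------------------------------------------------------------------

def generate_decoy_collection(
    n_systems: int = 49,
    n_relaxed: int = 20,
    n_decoys: int = 100,
    *,
    margin: float = 10.0,
    decoy_spread: float = 15.0,
    relaxed_jitter: float = 2.0,
    chain_length_range: tuple[int, int] = (50, 146),
    polar_per_residue: float = 50 / 76,
    nonpolar_per_residue: float = 42 / 76,
    contact_loss: float = 0.15,
    contact_gain: float = 0.05,
    error_table: MethodErrorTable | None = None,
    seed: int = 0,
) -> tuple[list[DecoySystem], FixtureManifest]:
    """Generate a decoy collection with a planted funnel and planted errors.

    Each system holds 1 native + ``n_relaxed`` relaxed natives +
    ``n_decoys`` decoys (the published Rosetta-set layout is 49 systems of
    1+20+100 = 121 structures, 5929 in total).  Chain lengths are uniform
    over 50-146 residues (the published range) and native contact counts
    scale with length at ubiquitin's rates (50 polar and 42 nonpolar per 76
    residues).  True energies place the native lowest: relaxed natives sit
    up to ``relaxed_jitter`` above it, the best decoy exactly ``margin``
    above it and the rest exponentially spread by ``decoy_spread``.

    Decoys lose a binomial fraction ``contact_loss`` of each native contact
    class and gain a fraction ``contact_gain`` of spurious contacts, so
    natives systematically carry more contacts than decoys.  When
    ``error_table`` is given, each structure's observed ``e_raw`` is its
    true energy plus one error per contact drawn from the table's per-class
    Gaussians; otherwise observed equals true.
    """
    if min(n_systems, n_relaxed, n_decoys) < 1:
        raise ValidationError("n_systems, n_relaxed and n_decoys must be >= 1")
    for name, val in [
        ("margin", margin),
        ("decoy_spread", decoy_spread),
        ("relaxed_jitter", relaxed_jitter),
    ]:
        if val < 0:
            raise ValidationError(f"{name} must be >= 0")
    if not (0 <= contact_loss <= 1 and 0 <= contact_gain <= 1):
        raise ValidationError("contact_loss/contact_gain must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def planted_error(counts: ContactCounts) -> float:
        if error_table is None:
            return 0.0
        total = 0.0
        for cls, n in counts.items():
            if n == 0:
                continue
            pdf = error_table.get(cls)
            total += float(rng.normal(pdf.mu, pdf.sigma, size=n).sum())
        return total

    systems = []
    for s in range(n_systems):
        sys_id = f"sys{s:02d}"
        length = int(rng.integers(chain_length_range[0], chain_length_range[1] + 1))
        nat_counts = ContactCounts.of(
            nonpolar=round(nonpolar_per_residue * length),
            polar=round(polar_per_residue * length),
        )
        e_native = -1.5 * length  # arbitrary stability scale, kcal/mol
        records = [
            FoldRecord(
                structure_id=f"{sys_id}_native",
                role=NATIVE,
                chain_length=length,
                counts=nat_counts,
                e_raw=e_native + planted_error(nat_counts),
            )
        ]
        for k in range(n_relaxed):
            e_true = e_native + float(rng.uniform(0, relaxed_jitter))
            records.append(
                FoldRecord(
                    structure_id=f"{sys_id}_rel{k:03d}",
                    role=RELAXED,
                    chain_length=length,
                    counts=nat_counts,
                    e_raw=e_true + planted_error(nat_counts),
                )
            )
        extras = rng.exponential(decoy_spread, size=n_decoys)
        extras -= extras.min()  # best decoy sits exactly `margin` above native
        for k in range(n_decoys):
            counts = ContactCounts(
                {
                    cls: int(rng.binomial(n, 1 - contact_loss))
                    + int(rng.binomial(n, contact_gain))
                    for cls, n in nat_counts.items()
                }
            )
            e_true = e_native + margin + float(extras[k])
            records.append(
                FoldRecord(
                    structure_id=f"{sys_id}_dec{k:03d}",
                    role=DECOY,
                    chain_length=length,
                    counts=counts,
                    e_raw=e_true + planted_error(counts),
                )
            )
        systems.append(DecoySystem(system_id=sys_id, records=tuple(records)))

    manifest = FixtureManifest(
        kind="decoy_collection",
        seed=seed,
        arguments={
            "n_systems": n_systems,
            "n_relaxed": n_relaxed,
            "n_decoys": n_decoys,
            "margin": margin,
            "decoy_spread": decoy_spread,
            "relaxed_jitter": relaxed_jitter,
            "contact_loss": contact_loss,
            "contact_gain": contact_gain,
            "error_table": None if error_table is None else error_table.method,
            "seed": seed,
        },
        planted={
            "margin": margin,
            "n_records": n_systems * (1 + n_relaxed + n_decoys),
            "error_class_params": {
                cls: {"mu": pdf.mu, "sigma2": pdf.sigma2}
                for cls, pdf in (error_table.pdfs.items() if error_table else [])
            },
        },
    )
    return systems, manifest
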