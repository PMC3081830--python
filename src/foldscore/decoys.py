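"""Native-vs-decoy discrimination metrics and collection-level analysis.

A decoy system is one protein: its crystal (native) structure, optionally
several relaxed versions of it, and a set of computationally generated
decoy conformations, each with a raw energy from some scoring method.
Three discrimination metrics are computed before and after systematic
error correction:

* EGAP  — lowest decoy energy minus lowest native energy (kcal/mol);
  positive and large when the native fold scores best.
* z-score — (lowest native energy - mean energy of all folds) / standard
  deviation of all fold energies; more negative is better.
* EBO   — error-bar overlap: whether the best native lies within the
  random-error bar of the lowest-energy structure, i.e. whether the method
  can distinguish them at all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errormodel import (
    NONPOLAR,
    POLAR,
    ContactCounts,
    MethodErrorTable,
    correct_energy,
    propagate_random,
)
from .exceptions import DegenerateInputError, ParseError, ValidationError

__all__ = [
    "ROLES",
    "FoldRecord",
    "DecoySystem",
    "DiscriminationReport",
    "egap",
    "zscore",
    "ebo",
    "apply_corrections",
    "evaluate_collection",
    "random_error_series",
    "random_error_scaling_exponent",
    "read_decoy_table",
    "write_decoy_table",
]

NATIVE = "native"
RELAXED = "relaxed_native"
DECOY = "decoy"
ROLES = (NATIVE, RELAXED, DECOY)
_NATIVE_ROLES = (NATIVE, RELAXED)


@dataclass(frozen=True)
class FoldRecord:
    """One scored structure of a decoy system."""

    structure_id: str
    role: str
    chain_length: int
    counts: ContactCounts
    e_raw: float
    e_corrected: float | None = None
    random_bar: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.chain_length < 0:
            raise ValidationError("chain_length must be >= 0")
        if self.e_corrected is not None and self.random_bar is None:
            raise ValidationError(
                "a corrected energy must carry its random-error bar"
            )

    def energy(self, which: str) -> float:
        """Select ``"e_raw"`` or ``"e_corrected"`` (the latter must exist)."""
        if which == "e_raw":
            return self.e_raw
        if which == "e_corrected":
            if self.e_corrected is None:
                raise ValidationError(
                    f"record {self.structure_id!r} has no corrected energy"
                )
            return self.e_corrected
        raise ValidationError(f"unknown energy field {which!r}")

    @property
    def is_native_like(self) -> bool:
        return self.role in _NATIVE_ROLES


@dataclass(frozen=True)
class DecoySystem:
    """One protein's natives, relaxed natives and decoys."""

    system_id: str
    records: tuple[FoldRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not any(r.is_native_like for r in self.records):
            raise ValidationError(
                f"system {self.system_id!r} has no native/relaxed_native record"
            )
        if not any(r.role == DECOY for r in self.records):
            raise ValidationError(f"system {self.system_id!r} has no decoy record")

    def natives(self) -> list[FoldRecord]:
        return [r for r in self.records if r.is_native_like]

    def decoys(self) -> list[FoldRecord]:
        return [r for r in self.records if r.role == DECOY]


def egap(system: DecoySystem, energy_field: str = "e_raw") -> float:
    """Energy gap: min decoy energy minus min native energy.

    Positive means every decoy scores above the best native (success);
    larger is better.
    """
    min_dec = min(r.energy(energy_field) for r in system.decoys())
    min_nat = min(r.energy(energy_field) for r in system.natives())
    return min_dec - min_nat


def zscore(system: DecoySystem, energy_field: str = "e_raw") -> float:
    """Discrimination z-score of the best native against all folds.

    (lowest native energy - mean of all fold energies) / sd of all fold
    energies (n-1 denominator).  More negative is better.  Raises
    :class:`DegenerateInputError` when the energies have zero spread.
    """
    energies = np.array([r.energy(energy_field) for r in system.records])
    if len(energies) < 2:
        raise DegenerateInputError("z-score needs at least 2 records")
    sd = float(energies.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError(
            f"system {system.system_id!r}: all energies equal, z-score undefined"
        )
    min_nat = min(r.energy(energy_field) for r in system.natives())
    return (min_nat - float(energies.mean())) / sd


def ebo(
    system: DecoySystem,
    energy_field: str = "e_raw",
    *,
    symmetric: bool = False,
) -> bool:
    """Error-bar overlap: does the best native overlap the global minimum?

    True when the lowest-energy record is itself native-like, or when the
    best native's energy lies within the random-error bar of the
    lowest-energy record.  With ``symmetric=True`` the native's own bar is
    added to the overlap window as well (two-bar overlap; not the default).
    """
    lowest = min(system.records, key=lambda r: r.energy(energy_field))
    if lowest.is_native_like:
        return True
    best_nat = min(system.natives(), key=lambda r: r.energy(energy_field))
    if lowest.random_bar is None:
        raise ValidationError(
            f"record {lowest.structure_id!r} carries no random-error bar; "
            "apply corrections first"
        )
    window = lowest.random_bar
    if symmetric:
        if best_nat.random_bar is None:
            raise ValidationError(
                f"record {best_nat.structure_id!r} carries no random-error bar"
            )
        window += best_nat.random_bar
    return best_nat.energy(energy_field) <= lowest.energy(energy_field) + window


def apply_corrections(
    system: DecoySystem, table: MethodErrorTable
) -> DecoySystem:
    """Return a copy with systematic corrections and random bars filled in."""
    corrected = []
    for r in system.records:
        ce = correct_energy(r.e_raw, r.counts, table)
        corrected.append(
            replace(r, e_corrected=ce.e_corrected, random_bar=ce.estimate.random)
        )
    return DecoySystem(system_id=system.system_id, records=tuple(corrected))


@dataclass
class DiscriminationReport:
    """Per-system metrics before/after correction plus improvement counts."""

    per_system: pd.DataFrame
    method: str

    @property
    def n_systems(self) -> int:
        return len(self.per_system)

    @property
    def n_records(self) -> int:
        return int(self.per_system["n_records"].sum())

    @property
    def egap_improved(self) -> int:
        return int(self.per_system["egap_improved"].sum())

    @property
    def zscore_improved(self) -> int:
        return int(self.per_system["zscore_improved"].sum())

    @property
    def ebo_true_corrected(self) -> int:
        return int(self.per_system["ebo_corrected"].sum())

    def summary(self) -> str:
        return (
            f"method {self.method}: {self.n_systems} systems, "
            f"{self.n_records} structures\n"
            f"  EGAP improved by correction: {self.egap_improved}/{self.n_systems}\n"
            f"  z-score improved by correction: {self.zscore_improved}/{self.n_systems}\n"
            f"  EBO true after correction: {self.ebo_true_corrected}/{self.n_systems}\n"
        )

    def to_csv(self, path: str | Path, *, delimiter: str = ",") -> None:
        self.per_system.to_csv(path, sep=delimiter, index=False)


def evaluate_collection(
    systems: Sequence[DecoySystem], table: MethodErrorTable
) -> DiscriminationReport:
    """Correct every record and score all three metrics raw vs corrected.

    A system counts as improved by EGAP when the corrected gap is strictly
    larger than the raw one, and by z-score when the corrected z-score is
    strictly more negative; ties count as no improvement.  EBO is reported
    as the number of systems where it holds after correction.
    """
    rows = []
    for system in systems:
        sysc = apply_corrections(system, table)
        eg_raw = egap(sysc, "e_raw")
        eg_cor = egap(sysc, "e_corrected")
        z_raw = zscore(sysc, "e_raw")
        z_cor = zscore(sysc, "e_corrected")
        rows.append(
            {
                "system_id": system.system_id,
                "n_records": len(system.records),
                "egap_raw": eg_raw,
                "egap_corrected": eg_cor,
                "egap_improved": eg_cor > eg_raw,
                "zscore_raw": z_raw,
                "zscore_corrected": z_cor,
                "zscore_improved": z_cor < z_raw,
                "ebo_raw": ebo(sysc, "e_raw"),
                "ebo_corrected": ebo(sysc, "e_corrected"),
            }
        )
    return DiscriminationReport(per_system=pd.DataFrame(rows), method=table.method)


def random_error_series(
    records: Iterable[FoldRecord], table: MethodErrorTable
) -> list[tuple[int, float]]:
    """Propagated random error vs chain length, one point per record.

    Because random errors accumulate in quadrature, folds whose contact
    counts grow linearly with chain length show error bars growing as the
    square root of length.
    """
    return [
        (r.chain_length, propagate_random(r.counts, table)) for r in records
    ]


def random_error_scaling_exponent(series: Sequence[tuple[int, float]]) -> float:
    """Least-squares log-log slope of random error vs chain length."""
    pts = [(length, err) for length, err in series if length > 0 and err > 0]
    if len(pts) < 2:
        raise DegenerateInputError(
            "need >= 2 positive points to fit a scaling exponent"
        )
    x = np.log([p[0] for p in pts])
    y = np.log([p[1] for p in pts])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "system_id",
    "structure_id",
    "role",
    "chain_length",
    "n_nonpolar",
    "n_polar",
    "e_raw",
]


def read_decoy_table(path: str | Path, *, delimiter: str = ",") -> list[DecoySystem]:
    """Read a decoy energy table (delimited text) into systems."""
    try:
        df = pd.read_csv(path, sep=delimiter)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot parse decoy table {path}: {exc}") from exc
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"decoy table {path} is missing columns {missing}")
    systems = []
    for system_id, group in df.groupby("system_id", sort=True):
        records = [
            FoldRecord(
                structure_id=str(row.structure_id),
                role=str(row.role),
                chain_length=int(row.chain_length),
                counts=ContactCounts.of(
                    nonpolar=int(row.n_nonpolar), polar=int(row.n_polar)
                ),
                e_raw=float(row.e_raw),
            )
            for row in group.itertuples(index=False)
        ]
        systems.append(DecoySystem(system_id=str(system_id), records=tuple(records)))
    return systems


def write_decoy_table(
    systems: Iterable[DecoySystem], path: str | Path, *, delimiter: str = ","
) -> None:
    rows = []
    for system in systems:
        for r in system.records:
            rows.append(
                {
                    "system_id": system.system_id,
                    "structure_id": r.structure_id,
                    "role": r.role,
                    "chain_length": r.chain_length,
                    "n_nonpolar": r.counts[NONPOLAR],
                    "n_polar": r.counts[POLAR],
                    "e_raw": r.e_raw,
                }
            )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep=delimiter, index=False)
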