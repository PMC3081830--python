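"""Gaussian error models for fragment interaction energies and their
propagation through whole protein folds.

A scoring method's per-interaction errors (approximate minus reference
interaction energy, kcal/mol) are modelled as a Gaussian per interaction
class with mean ``mu`` (the systematic, correctable component) and variance
``sigma2`` (the random component).  For a fold containing ``N_i``
interactions of class *i*:

* total systematic error  =  sum_i N_i * mu_i          (simple sum)
* total random error      =  sqrt(sum_i N_i * sigma_i^2)  (root sum of squares)

The systematic total is subtracted from a raw score; the random total is
reported alongside it as a 1-sigma error bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import (
    InsufficientDataError,
    TableLookupError,
    ValidationError,
)

__all__ = [
    "NONPOLAR",
    "POLAR",
    "ALL",
    "INTERACTION_CLASSES",
    "DeviationRecord",
    "ErrorPDF",
    "MethodErrorTable",
    "ContactCounts",
    "ErrorEstimate",
    "CorrectedEnergy",
    "fit_error_pdf",
    "r_factor",
    "propagate_systematic",
    "propagate_random",
    "correct_energy",
    "read_deviation_database",
    "write_deviation_database",
]

#: Interaction-class vocabulary.  ``nonpolar`` covers van der Waals contacts,
#: ``polar`` covers hydrogen bonds; ``all`` pools every interaction and is used
#: only when contacts cannot be classified.
NONPOLAR = "nonpolar"
POLAR = "polar"
ALL = "all"
INTERACTION_CLASSES = (NONPOLAR, POLAR, ALL)

_CONSISTENCY_TOL = 1e-9


def _check_class(label: str, *, allow_all: bool = True) -> str:
    if not isinstance(label, str) or not label:
        raise ValidationError("interaction class label must be a non-empty string")
    allowed = INTERACTION_CLASSES if allow_all else (NONPOLAR, POLAR)
    if label not in allowed:
        raise ValidationError(
            f"unknown interaction class {label!r}; expected one of {allowed}"
        )
    return label


@dataclass(frozen=True)
class DeviationRecord:
    """One fragment pair's approximate-vs-reference energy comparison.

    ``deviation`` is SIGNED: ``e_approx - e_ref`` in kcal/mol.  If omitted it
    is computed; if given it is cross-checked to 1e-9 kcal/mol.
    """

    fragment_id: str
    interaction_class: str
    e_approx: float
    e_ref: float
    deviation: float | None = None

    def __post_init__(self) -> None:
        _check_class(self.interaction_class, allow_all=False)
        expected = self.e_approx - self.e_ref
        if self.deviation is None:
            object.__setattr__(self, "deviation", expected)
        elif abs(self.deviation - expected) > _CONSISTENCY_TOL:
            raise ValidationError(
                f"record {self.fragment_id!r}: stored deviation "
                f"{self.deviation} != e_approx - e_ref = {expected}"
            )


@dataclass(frozen=True)
class ErrorPDF:
    """Gaussian error model for one interaction class under one method.

    ``mu`` is the mean signed error per interaction (kcal/mol); ``sigma2``
    the variance of the errors ((kcal/mol)^2).  ``n_samples`` is 0 when the
    parameters come from a published table rather than a fit.
    """

    method: str
    interaction_class: str
    mu: float
    sigma2: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        _check_class(self.interaction_class)
        if not math.isfinite(self.mu) or not math.isfinite(self.sigma2):
            raise ValidationError("mu and sigma2 must be finite")
        if self.sigma2 < 0:
            raise ValidationError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.n_samples < 0:
            raise ValidationError("n_samples must be >= 0")

    @property
    def sigma(self) -> float:
        """Standard deviation of the per-interaction errors (kcal/mol)."""
        return math.sqrt(self.sigma2)


@dataclass(frozen=True)
class MethodErrorTable:
    """Per-interaction-class error PDFs for one scoring method.

    Lookup of a class absent from the mapping raises
    :class:`~foldscore.exceptions.TableLookupError` — never a silent zero.
    """

    method: str
    pdfs: Mapping[str, ErrorPDF]
    r_factor: float | None = None

    def __post_init__(self) -> None:
        if not self.method:
            raise ValidationError("method label must be non-empty")
        for cls, pdf in self.pdfs.items():
            _check_class(cls)
            if pdf.method != self.method:
                raise ValidationError(
                    f"pdf for class {cls!r} carries method {pdf.method!r}, "
                    f"table is {self.method!r}"
                )
            if pdf.interaction_class != cls:
                raise ValidationError(
                    f"pdf stored under {cls!r} is labelled {pdf.interaction_class!r}"
                )
        if self.r_factor is not None and self.r_factor < 0:
            raise ValidationError("r_factor must be non-negative")

    def get(self, interaction_class: str) -> ErrorPDF:
        try:
            return self.pdfs[interaction_class]
        except KeyError:
            raise TableLookupError(
                f"method {self.method!r} has no error PDF for interaction "
                f"class {interaction_class!r} (available: {sorted(self.pdfs)})"
            ) from None


@dataclass(frozen=True)
class ContactCounts:
    """Per-interaction-class contact tallies N_i for one structure."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for cls, n in dict(self.counts).items():
            _check_class(cls)
            if int(n) != n or n < 0:
                raise ValidationError(f"count for {cls!r} must be a non-negative integer")
            clean[cls] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def of(cls, nonpolar: int = 0, polar: int = 0) -> "ContactCounts":
        return cls({NONPOLAR: nonpolar, POLAR: polar})

    def __getitem__(self, interaction_class: str) -> int:
        return self.counts.get(interaction_class, 0)

    def items(self):
        return self.counts.items()

    def total(self) -> int:
        return sum(self.counts.values())

    def scaled(self, k: int) -> "ContactCounts":
        if k < 0:
            raise ValidationError("scale factor must be non-negative")
        return ContactCounts({c: n * k for c, n in self.counts.items()})

    def __add__(self, other: "ContactCounts") -> "ContactCounts":
        merged = dict(self.counts)
        for c, n in other.counts.items():
            merged[c] = merged.get(c, 0) + n
        return ContactCounts(merged)


@dataclass(frozen=True)
class ErrorEstimate:
    """Propagated systematic (signed) and random (>=0) error for one fold."""

    systematic: float
    random: float
    counts_used: ContactCounts
    method: str

    def __post_init__(self) -> None:
        if self.random < 0:
            raise ValidationError("random error must be non-negative")


@dataclass(frozen=True)
class CorrectedEnergy:
    """Raw score, its error estimate and the systematic-corrected score.

    The correction is a single application: calling :func:`correct_energy`
    on an already-corrected value subtracts the systematic total again.
    """

    e_raw: float
    estimate: ErrorEstimate
    e_corrected: float

    def __post_init__(self) -> None:
        expected = self.e_raw - self.estimate.systematic
        if abs(self.e_corrected - expected) > _CONSISTENCY_TOL:
            raise ValidationError(
                f"e_corrected {self.e_corrected} != e_raw - systematic = {expected}"
            )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_error_pdf(
    records: Sequence[DeviationRecord],
    interaction_class: str,
    *,
    method: str = "fitted",
) -> ErrorPDF:
    """Fit a Gaussian error PDF by moment matching.

    ``mu`` is the sample mean of the signed deviations and ``sigma2`` the
    unbiased (n-1) sample variance.  Class ``"all"`` pools every record;
    otherwise only records of the requested class are used.  At least two
    matching records are required.
    """
    _check_class(interaction_class)
    if interaction_class == ALL:
        devs = [r.deviation for r in records]
    else:
        devs = [r.deviation for r in records if r.interaction_class == interaction_class]
    k = len(devs)
    if k < 2:
        raise InsufficientDataError(
            f"need >= 2 records of class {interaction_class!r} to fit a "
            f"variance, got {k}"
        )
    mean = sum(devs) / k
    var = sum((d - mean) ** 2 for d in devs) / (k - 1)
    return ErrorPDF(
        method=method,
        interaction_class=interaction_class,
        mu=mean,
        sigma2=var,
        n_samples=k,
    )


def r_factor(records: Sequence[DeviationRecord]) -> float:
    """Aggregate relative residual sum(|e_approx - e_ref|) / sum(|e_ref|).

    Analogous to the residual minimised in crystallographic refinement,
    applied to fragment interaction energies.  The exact formula is this
    package's reconstruction; values below ~0.1 indicate a method whose
    fragment energies track the reference closely.
    """
    if not records:
        raise ValidationError("r_factor requires a non-empty record list")
    denom = sum(abs(r.e_ref) for r in records)
    if denom == 0:
        raise ValidationError(
            "r_factor undefined: all reference energies are zero"
        )
    num = sum(abs(r.deviation) for r in records)
    return num / denom


# ---------------------------------------------------------------------------
# propagation & correction
# ---------------------------------------------------------------------------

def propagate_systematic(counts: ContactCounts, table: MethodErrorTable) -> float:
    """Total systematic error sum_i N_i * mu_i (kcal/mol, signed).

    Systematic errors are predictable in sign and magnitude and accumulate
    as a simple sum; the result is subtractable from a raw score.
    """
    total = 0.0
    for cls, n in counts.items():
        if n == 0:
            continue
        total += n * table.get(cls).mu
    return total


def propagate_random(counts: ContactCounts, table: MethodErrorTable) -> float:
    """Total random error sqrt(sum_i N_i * sigma_i^2) (kcal/mol, >= 0).

    Random errors are unpredictable in sign and accumulate in quadrature;
    the result is a 1-sigma error bar on the total energy.
    """
    ss = 0.0
    for cls, n in counts.items():
        if n == 0:
            continue
        pdf = table.get(cls)
        ss += n * pdf.sigma2
    return math.sqrt(ss)


def estimate_errors(counts: ContactCounts, table: MethodErrorTable) -> ErrorEstimate:
    """Propagate both error components for a fold with the given contacts."""
    return ErrorEstimate(
        systematic=propagate_systematic(counts, table),
        random=propagate_random(counts, table),
        counts_used=counts,
        method=table.method,
    )


def correct_energy(
    e_raw: float, counts: ContactCounts, table: MethodErrorTable
) -> CorrectedEnergy:
    """Subtract the propagated systematic error from a raw score.

    Returns the corrected score with its 1-sigma random-error bar.  Pure and
    single-application: correcting an already-corrected energy subtracts the
    systematic total a second time.
    """
    est = estimate_errors(counts, table)
    return CorrectedEnergy(
        e_raw=e_raw, estimate=est, e_corrected=e_raw - est.systematic
    )


# ---------------------------------------------------------------------------
# deviation-database IO (delimited text)
# ---------------------------------------------------------------------------

_DB_COLUMNS = ["fragment_id", "interaction_class", "e_approx", "e_ref"]


def read_deviation_database(
    path: str | Path, *, delimiter: str = ","
) -> list[DeviationRecord]:
    """Read a deviation database from delimited text.

    Expected header columns: ``fragment_id, interaction_class, e_approx,
    e_ref`` and optionally a precomputed ``deviation`` column which is
    cross-checked against ``e_approx - e_ref``.
    """
    try:
        df = pd.read_csv(path, sep=delimiter)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        from .exceptions import ParseError

        raise ParseError(f"cannot parse deviation database {path}: {exc}") from exc
    missing = [c for c in _DB_COLUMNS if c not in df.columns]
    if missing:
        from .exceptions import ParseError

        raise ParseError(
            f"deviation database {path} is missing columns {missing}; "
            f"found {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DeviationRecord(
                fragment_id=str(row.fragment_id),
                interaction_class=str(row.interaction_class),
                e_approx=float(row.e_approx),
                e_ref=float(row.e_ref),
                deviation=float(row.deviation) if hasattr(row, "deviation") else None,
            )
        )
    return records


def write_deviation_database(
    records: Iterable[DeviationRecord], path: str | Path, *, delimiter: str = ","
) -> None:
    """Write records as delimited text with a precomputed deviation column."""
    df = pd.DataFrame(
        [
            {
                "fragment_id": r.fragment_id,
                "interaction_class": r.interaction_class,
                "e_approx": r.e_approx,
                "e_ref": r.e_ref,
                "deviation": r.deviation,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep=delimiter, index=False)
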