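"""Reading, writing and packaging of method error tables.

Error tables are human-editable YAML files: a method label, an optional
R-factor, and per-interaction-class Gaussian parameters.  The statistics for
twenty scoring methods evaluated on the ubiquitin (1UBQ) fragment database —
force fields, semiempirical Hamiltonians, HF, MP2 and DFT at several basis
sets — ship with the package, exactly as published, plus one extra table
("B97-D/TZVP (text)") carrying the worked-example-precision values quoted in
running text rather than the rounded tabulated ones.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errormodel import ErrorPDF, MethodErrorTable
from .exceptions import ParseError, UnknownMethodError, ValidationError

__all__ = [
    "load_error_table",
    "write_error_table",
    "available_methods",
    "format_error_table",
]

_CLASS_ORDER = ("nonpolar", "polar", "all")
_DATA_PACKAGE = "foldscore.data.error_tables"


def _data_dir():
    return resources.files(_DATA_PACKAGE)


def _registry() -> dict[str, Path]:
    """Map packaged method labels to their YAML files (scanned once)."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        reg: dict[str, Path] = {}
        for entry in sorted(_data_dir().iterdir(), key=lambda e: e.name):
            if not entry.name.endswith(".yaml"):
                continue
            with entry.open("r") as fh:
                doc = yaml.safe_load(fh)
            reg[str(doc["method"])] = Path(str(entry))
        _REGISTRY_CACHE = reg
    return _REGISTRY_CACHE


_REGISTRY_CACHE: dict[str, Path] | None = None


def available_methods() -> list[str]:
    """Labels of all packaged method error tables."""
    return sorted(_registry())


def _table_from_doc(doc: dict, origin: str) -> MethodErrorTable:
    if not isinstance(doc, dict) or "method" not in doc or "classes" not in doc:
        raise ParseError(f"{origin}: expected keys 'method' and 'classes'")
    method = str(doc["method"])
    pdfs = {}
    classes = doc["classes"]
    if not isinstance(classes, dict) or not classes:
        raise ParseError(f"{origin}: 'classes' must be a non-empty mapping")
    for cls, params in classes.items():
        try:
            pdfs[cls] = ErrorPDF(
                method=method,
                interaction_class=str(cls),
                mu=float(params["mu"]),
                sigma2=float(params["sigma2"]),
                n_samples=int(params.get("n", 0)),
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(
                f"{origin}: class {cls!r} needs numeric 'mu' and 'sigma2' ({exc})"
            ) from exc
    rf = doc.get("r_factor")
    return MethodErrorTable(
        method=method, pdfs=pdfs, r_factor=None if rf is None else float(rf)
    )


def load_error_table(source: str | Path) -> MethodErrorTable:
    """Load a method error table from a packaged name or a YAML file path.

    ``source`` is first matched against the packaged method labels (e.g.
    ``"B97-D/TZVP"``, ``"FF99SB"``); otherwise it is treated as a file path.
    An unknown name raises :class:`UnknownMethodError` listing the packaged
    methods.
    """
    reg = _registry()
    if str(source) in reg:
        path = reg[str(source)]
    else:
        path = Path(source)
        if not path.is_file():
            raise UnknownMethodError(
                f"no packaged method or readable file {source!r}; packaged "
                f"methods: {available_methods()}"
            )
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParseError(f"malformed error table {path}{line}: {exc}") from exc
    return _table_from_doc(doc, str(path))


def _fmt(x: float) -> str:
    """Canonical float formatting (shortest repr round-trip)."""
    return repr(float(x))


def format_error_table(table: MethodErrorTable) -> str:
    """Render a table in the canonical YAML layout used by the writer.

    The layout is deterministic, so ``format(load(path))`` reproduces a file
    previously produced by :func:`write_error_table` byte for byte.
    """
    lines = [f"method: {table.method!r}"]
    if table.r_factor is not None:
        lines.append(f"r_factor: {_fmt(table.r_factor)}")
    lines.append("classes:")
    ordered = [c for c in _CLASS_ORDER if c in table.pdfs] + sorted(
        c for c in table.pdfs if c not in _CLASS_ORDER
    )
    for cls in ordered:
        pdf = table.pdfs[cls]
        lines.append(
            f"  {cls}: {{mu: {_fmt(pdf.mu)}, sigma2: {_fmt(pdf.sigma2)}, "
            f"n: {pdf.n_samples}}}"
        )
    return "\n".join(lines) + "\n"


def write_error_table(table: MethodErrorTable, path: str | Path) -> None:
    """Write a table as canonical YAML (see :func:`format_error_table`)."""
    if not table.pdfs:
        raise ValidationError("refusing to write a table with no classes")
    Path(path).write_text(format_error_table(table))
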