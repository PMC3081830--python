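"""Exception hierarchy.

Everything raised on purpose derives from :class:`FoldscoreError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class FoldscoreError(Exception):
    """Base class for all errors raised by foldscore."""


class ValidationError(FoldscoreError, ValueError):
    """Invalid value for a domain object or operation parameter."""


class InsufficientDataError(FoldscoreError):
    """Too few records to estimate the requested statistic."""


class TableLookupError(FoldscoreError, KeyError):
    """An interaction class required for propagation is absent from the table."""


class UnknownMethodError(FoldscoreError, KeyError):
    """A packaged method name was requested that does not exist."""


class DegenerateInputError(FoldscoreError):
    """Input is structurally valid but degenerate (e.g. zero energy spread)."""


class StructureError(FoldscoreError):
    """A protein structure cannot be parsed or fails a structural precondition."""


class MissingHydrogensError(StructureError):
    """Hydrogen-bond detection requires explicit hydrogens."""


class UnknownElementError(StructureError):
    """An element has no entry in the radius table in use."""


class FragmentError(FoldscoreError):
    """Fragment selection or link-atom capping failed."""


class ParseError(FoldscoreError):
    """A delimited-text or config file is malformed."""
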