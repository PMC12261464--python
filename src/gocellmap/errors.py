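"""Exception hierarchy shared across the package.

Each class maps to a CLI exit code: usage errors exit 2, data/format errors
exit 3, integrity errors exit 4.
"""


class GoCellMapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(GoCellMapError):
    """Bad parameters or unknown option values."""

    exit_code = 2


class FormatError(GoCellMapError):
    """A file does not conform to its declared format."""

    exit_code = 3


class DataError(GoCellMapError):
    """Inputs are well-formed but empty/inconsistent for the requested step."""

    exit_code = 3


class LookupError_(GoCellMapError):
    """An identifier (term, gene, cell type) cannot be resolved."""

    exit_code = 3


class IntegrityError(GoCellMapError):
    """Structural corruption: cycles in the ontology, mismatched universes."""

    exit_code = 4
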