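"""Exception hierarchy shared across the package.

Every error raised by metgge derives from :class:`MetggeError` so callers
(and the CLI) can distinguish configuration, data and analysis failures.
"""


class MetggeError(Exception):
    """Base class for all metgge errors."""


class SchemaError(MetggeError):
    """A required column or trait is missing, or a spec is inconsistent."""


class ParseError(MetggeError):
    """A cell could not be parsed as a number; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DuplicateRecordError(MetggeError):
    """The same (genotype, environment, replicate) triple occurs twice."""


class BalanceError(MetggeError):
    """The trial layout is unbalanced; offending cells are attached."""

    def __init__(self, message: str, cells: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.cells = cells or []


class ConfigError(MetggeError):
    """Invalid simulation or pipeline configuration."""


class DomainError(MetggeError):
    """A parameter is outside its mathematical domain (e.g. h2 > 1)."""


class DegenerateGeometryError(MetggeError):
    """Biplot geometry is degenerate (collinear points, zero AEC vector)."""


class NotApplicableError(MetggeError):
    """An operation was requested on a configuration that does not define it."""
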