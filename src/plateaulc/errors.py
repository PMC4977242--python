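"""Exception hierarchy for plateaulc.

All errors raised by the library derive from :class:`PlateauLCError` so
callers (and the CLI) can catch the package's failures in one clause.
"""


class PlateauLCError(Exception):
    """Base class for all plateaulc errors."""


class SchemaError(PlateauLCError):
    """A required column is missing or the column mapping is invalid."""


class RowError(PlateauLCError):
    """A data row failed validation; carries the 1-based file line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class DuplicateRecordError(PlateauLCError):
    """Two rows describe the same (subject_id, site) measurement."""


class InsufficientReplicatesError(PlateauLCError):
    """A subject has fewer repeated measurements than required."""


class InsufficientDataError(PlateauLCError):
    """Too few subjects (or values) for the requested computation."""


class DomainError(PlateauLCError):
    """Arguments outside the mathematical domain of an operation."""


class ConfigError(PlateauLCError):
    """Invalid simulation or analysis configuration; lists all violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration: " + "; ".join(self.violations))


class SplitError(PlateauLCError):
    """An early/late split would leave one side empty."""
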