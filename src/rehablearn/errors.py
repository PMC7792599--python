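"""Exception hierarchy shared across the package."""


class RehabLearnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RehabLearnError):
    """A file or table is missing a required column or field."""


class ParseError(RehabLearnError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class TaxonomyError(RehabLearnError):
    """A label value is not part of the declared taxonomy."""


class ValidationError(RehabLearnError):
    """A value violates a hard invariant (negative sigma, bad fraction, ...)."""


class DomainError(RehabLearnError):
    """A numeric argument is outside the mathematical domain of an operation."""


class InsufficientDataError(RehabLearnError):
    """Too few records to perform the requested operation."""


class StateError(RehabLearnError):
    """Operation invoked in the wrong pipeline state (e.g. unnormalized input)."""


class StratificationError(RehabLearnError):
    """A class is too small to survive stratified splitting/folding."""


class InfeasibleStatsError(RehabLearnError):
    """Requested moment targets cannot be met with physical (positive) values."""


class ConfigError(RehabLearnError):
    """Unknown or inconsistent configuration value."""
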