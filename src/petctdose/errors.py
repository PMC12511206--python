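"""Exception hierarchy for the dose-audit pipeline.

Exit-code mapping used by the CLI: validation/configuration problems and
computation failures raise distinct subclasses so callers can tell a bad
input file from a bug in a downstream calculation.
"""


class PetctDoseError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PetctDoseError, ValueError):
    """A scalar input violates a documented precondition (e.g. weight <= 0)."""


class EmptyInputError(PetctDoseError, ValueError):
    """An operation that needs at least one observation received none."""


class ConfigurationError(PetctDoseError):
    """A config object/file is internally inconsistent or names an unknown rule."""


class ValidationError(PetctDoseError):
    """A patient table violates the schema; carries the offending row indices."""

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = list(rows) if rows else []


class GenerationError(PetctDoseError):
    """A synthetic-cohort spec violates its invariants."""
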