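"""Exception hierarchy for karstocc.

All package-specific failures derive from :class:`KarstoccError` so callers
can catch one base class; validation errors additionally derive from
``ValueError`` because they signal bad input values.
"""

from __future__ import annotations


class KarstoccError(Exception):
    """Base class for all karstocc errors."""


class SchemaError(KarstoccError):
    """A required column, key, or field is missing or unknown."""


class DataValidationError(KarstoccError, ValueError):
    """An input value violates a documented invariant.

    ``rows`` carries 1-based data-row numbers (header excluded) when the
    error originated from a delimited file.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = list(rows) if rows else []
        if self.rows:
            message = f"{message} (rows: {', '.join(map(str, self.rows))})"
        super().__init__(message)


class ReferentialError(DataValidationError):
    """A record references an entity that does not exist, or is duplicated."""


class CompositionError(DataValidationError):
    """A land-use composition violates its simplex invariants."""


class TransformError(KarstoccError):
    """A covariate cannot be transformed (e.g. zero variance)."""


class ScreeningError(KarstoccError):
    """Covariate screening cannot be performed (too few complete rows)."""


class ConfigError(KarstoccError):
    """An invalid configuration value."""
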