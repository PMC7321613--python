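"""Exception hierarchy shared across the package."""


class LipothermError(Exception):
    """Base class for all package errors."""


class SchemaError(LipothermError):
    """An input table is missing a required column or uses an unknown dialect."""


class ValidationError(LipothermError):
    """A row violates a physical invariant (k <= 0, phi outside [0, 1], ...)."""


class InsufficientDataError(LipothermError):
    """Too few points for the requested fit (OLS needs n >= 3, van't Hoff n >= 4)."""


class DegenerateDesignError(LipothermError):
    """The regressor is constant; the slope is unidentifiable."""


class AmbiguousSeriesError(LipothermError):
    """A series mixes temperatures (isocratic fit) or modifier fractions (van't Hoff fit)."""


class PairingError(LipothermError):
    """A compound pair cannot be formed: mismatched modifiers, grids or compound sets."""
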