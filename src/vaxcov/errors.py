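"""Exception hierarchy.

Everything user-facing derives from :class:`VaxcovError` so the CLI can map
any input problem to a single exit code.
"""


class VaxcovError(Exception):
    """Base class for all package errors."""


class ValidationError(VaxcovError, ValueError):
    """An input value or structure violates a model precondition.

    ``field`` names the offending input where known.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message if field is None else f"{field}: {message}")


class CalibrationError(ValidationError):
    """Degenerate or contradictory calibration inputs (e.g. U_c = 1, C_c > M)."""


class MissingDataError(VaxcovError):
    """No usable indicator value at any priority for a region/barrier pair."""
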