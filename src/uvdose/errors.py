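"""Exception hierarchy.

Validation errors (bad inputs, malformed files) and numerical errors
(failed fits, non-convergent quadrature) are kept distinct so the CLI can
map them to different exit codes.
"""


class UVDoseError(Exception):
    """Base class for all package errors."""


class ValidationError(UVDoseError, ValueError):
    """An input violates a precondition (non-positive dimension, bad file)."""


class MediumOverflowError(ValidationError):
    """The medium column would be taller than the well wall."""


class InsufficientDataError(ValidationError):
    """Too few points or dose groups for the requested operation."""


class NumericalError(UVDoseError, RuntimeError):
    """A fit or quadrature failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
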