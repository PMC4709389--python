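"""Exception hierarchy shared across the package.

Each failure mode maps to a distinct exception so callers (and the CLI,
which translates them into exit codes) can discriminate schema problems
from numerical ones.
"""


class GastroPBPKError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(GastroPBPKError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateParameterError(GastroPBPKError, ValueError):
    """A parameter combination makes the model ill-defined
    (e.g. complex disposition exponents, zero dissociation rate)."""


class IntegrationFailureError(GastroPBPKError, RuntimeError):
    """The ODE solver failed to produce a trajectory."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitFailureError(GastroPBPKError, RuntimeError):
    """All optimization restarts failed or the design is under-determined."""


class SchemaError(GastroPBPKError, ValueError):
    """An input table or config violates the expected schema."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class NotFoundError(GastroPBPKError, LookupError):
    """A requested feature (e.g. a threshold crossing) does not exist."""


class ConfigurationError(GastroPBPKError, ValueError):
    """A pipeline configuration is inconsistent or incomplete."""
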