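"""Exception hierarchy for lgca_walks.

All package errors derive from :class:`LgcaError` so callers can catch one
base class; the CLI maps subclasses onto exit codes (config errors -> 2,
model-validity errors -> 3).
"""


class LgcaError(Exception):
    """Base class for all lgca_walks errors."""


class InvalidGeometryError(LgcaError):
    """Raised for unsupported lattice geometries (e.g. b < 2, non-square
    lattice requested for a square-lattice-only closed form)."""


class ParameterError(LgcaError):
    """Raised for non-finite or out-of-domain model parameters."""


class KernelValidityError(LgcaError):
    """Raised when a reorientation kernel produces an invalid probability
    vector (e.g. the linear kernel with |g| > 1/d).  Carries the step index
    at which the violation occurred when known."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ConfigError(LgcaError):
    """Raised for malformed run configurations (unknown keys, missing
    model parameters, schema violations)."""


class NumericsError(LgcaError):
    """Raised when a numerical routine (quadrature, classification) fails to
    converge or to reach its tolerance."""
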