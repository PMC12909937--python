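"""Exception hierarchy for lysoflow."""


class LysoflowError(Exception):
    """Base class for all lysoflow errors."""


class InvalidParameterError(LysoflowError, ValueError):
    """A physical parameter is outside its admissible range."""


class GeometryError(LysoflowError, ValueError):
    """A requested configuration is geometrically impossible (rod does not
    fit inside the lysosome, spacing smaller than a particle, ...)."""


class SolverError(LysoflowError, RuntimeError):
    """The flow solver failed to produce a solution within tolerance."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class StateError(LysoflowError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class IdentifiabilityError(LysoflowError, RuntimeError):
    """The requested parameter cannot be constrained by the data (e.g. all
    chain-count observations sit on a geometry-imposed cap, so the cohesion
    scale never enters the predictions)."""
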