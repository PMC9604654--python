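"""Exception hierarchy for pfasim."""


class PfaError(Exception):
    """Base class for all pfasim errors."""


class GeometryError(PfaError, ValueError):
    """Inconsistent scenario geometry (e.g. catheter inserted through the wall)."""


class ResolutionError(PfaError, ValueError):
    """Mesh resolution too coarse to represent the catheter."""


class DegenerateFiberError(PfaError, ValueError):
    """A fiber pattern produced a zero-norm direction."""


class DomainError(PfaError, ValueError):
    """Scalar input outside the physical domain of an operation."""


class NormalizationError(PfaError, ValueError):
    """A direction vector that must be unit length is not."""


class MissingFiberError(PfaError, ValueError):
    """Anisotropic conductivity requested without a fiber direction."""


class ConvergenceError(PfaError, RuntimeError):
    """Nonlinear iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class BoundaryTagError(PfaError, KeyError):
    """Unknown boundary/surface tag."""


class StabilityError(PfaError, RuntimeError):
    """Time step too coarse for the advective term."""


class DegenerateIsosurfaceError(PfaError, ValueError):
    """Field is constant and exactly at the threshold; isosurface undefined."""


class UndefinedPercentError(PfaError, ZeroDivisionError):
    """Percent difference requested with a zero reference value."""


class InsufficientDataError(PfaError, ValueError):
    """Aggregate statistics need at least two values."""


class ConfigError(PfaError, ValueError):
    """Invalid run configuration."""
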