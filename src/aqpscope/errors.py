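"""Exception hierarchy shared across aqpscope modules."""


class AqpscopeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AqpscopeError):
    """A file could not be parsed in the declared dialect."""


class GeometryError(AqpscopeError):
    """A geometric operation received degenerate or incomplete input."""


class AnnotationError(AqpscopeError):
    """Selectivity-filter positions could not be assigned."""


class AmbiguityError(AnnotationError):
    """Motif search produced zero or too many candidates."""


class DomainError(AqpscopeError):
    """An argument lies outside the mathematical domain of an operation."""


class AlignmentError(AqpscopeError):
    """Profiles or structures cannot be brought onto a common frame."""


class UnwrapError(AqpscopeError):
    """Periodic coordinates cannot be unwrapped (no box information)."""


class CoverageError(AqpscopeError):
    """Umbrella windows do not overlap along the reaction coordinate."""


class IterationError(AqpscopeError):
    """A self-consistent iteration failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TopologyError(AqpscopeError):
    """Required atoms or connectivity are missing from a topology."""


class FitError(AqpscopeError):
    """A nonlinear least-squares fit failed."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EstimateError(AqpscopeError):
    """An observable could not be estimated from the given trajectory."""


class ParameterError(AqpscopeError):
    """A generator or analysis parameter is invalid."""
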