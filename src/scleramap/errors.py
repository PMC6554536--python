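"""Exception hierarchy for scleramap."""


class ScleramapError(Exception):
    """Base class for all scleramap errors."""


class InvalidGeometryError(ScleramapError):
    """Mesh or point-cloud geometry violates a precondition."""


class NonManifoldError(InvalidGeometryError):
    """An edge is shared by more than two triangles."""


class InsufficientDataError(ScleramapError):
    """Not enough data points to perform the requested operation."""


class FlaggedElementError(ScleramapError):
    """A per-element computation produced a physically invalid value.

    Carries the offending element index in ``element_index``.
    """

    def __init__(self, message: str, element_index: int):
        super().__init__(message)
        self.element_index = element_index


class ParameterError(ScleramapError):
    """A numerical parameter is outside its admissible range."""


class ParseError(ScleramapError):
    """A file could not be parsed; message carries line/record context."""


class SingularElementError(FlaggedElementError):
    """Element degenerate (zero area / non-positive Jacobian) in some configuration."""


class EnergyOverflowError(ScleramapError):
    """The exponential fiber energy overflowed for the given state/parameters."""


class SolverFailureError(ScleramapError):
    """The nonlinear forward solver failed to converge.

    ``diverged`` marks an explosive divergence (residual growing without
    bound), for which load-increment refinement is pointless.
    """

    def __init__(self, message: str, diverged: bool = False):
        super().__init__(message)
        self.diverged = diverged


class OptimizationFailureError(ScleramapError):
    """The inverse optimization failed (all candidates infeasible)."""


class DegenerateSubdomainError(ScleramapError):
    """A subdomain has no interior nodes; no residual can be formed."""


class ConfigError(ScleramapError):
    """Run configuration invalid."""
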