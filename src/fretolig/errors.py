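"""Exception types shared across the package."""


class FretoligError(Exception):
    """Base class for package-specific errors."""


class ExtrapolationError(FretoligError, ValueError):
    """A lookup was requested outside the tabulated range."""


class SchemaError(FretoligError, ValueError):
    """An input table does not conform to the expected column schema."""


class InsufficientDesignError(FretoligError, ValueError):
    """The experimental design cannot support the requested analysis."""


class UndefinedMeasurementError(FretoligError, ValueError):
    """A donor-side quantity was requested for a donor-free population."""


class NonConvergenceError(FretoligError, RuntimeError):
    """Nonlinear refinement failed; carries the grid-search fallback values."""

    def __init__(self, message, grid_best=None):
        super().__init__(message)
        self.grid_best = grid_best
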