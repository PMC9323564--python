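"""Exception hierarchy shared across the pipeline stages."""


class GlyconetError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(GlyconetError):
    """A simulation design or study design violates its preconditions."""


class NormalizationError(GlyconetError):
    """Size-factor normalization is impossible (no gene expressed everywhere)."""


class InsufficientSamplesError(GlyconetError):
    """Too few samples for the requested correlation/leave-one-out operation."""


class FormatError(GlyconetError):
    """An input table violates the expected schema."""


class ConsistencyError(GlyconetError):
    """Two inputs that must describe the same genes/samples disagree."""


class ConvergenceError(GlyconetError):
    """An iterative procedure failed to converge.

    Carries the last residual in ``residual``.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class StageError(GlyconetError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
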