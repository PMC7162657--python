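"""Exception hierarchy used across the package."""


class CtrlEnergyError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CtrlEnergyError, ValueError):
    """Invalid user-supplied parameter or specification."""


class GenerationError(CtrlEnergyError):
    """Synthetic-cohort generation produced an invalid quantity."""


class ValidationError(CtrlEnergyError, ValueError):
    """Input data violates a structural invariant."""


class DegenerateInputError(CtrlEnergyError, ValueError):
    """Input is degenerate for the requested operation (e.g. an all-zero matrix)."""


class SolverError(CtrlEnergyError):
    """A linear solve or propagation failed numerically."""


class IllConditionedError(SolverError):
    """The shooting system is too ill-conditioned to trust the solution."""


class DegenerateTestError(CtrlEnergyError, ValueError):
    """A statistical test is undefined for the given data (e.g. zero-variance differences)."""


class UndefinedCorrelationError(CtrlEnergyError, ValueError):
    """Correlation undefined because a residual vector is constant."""
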