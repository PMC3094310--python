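"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2, NumericalError -> 3.
"""


class MixtoxError(Exception):
    """Base class for all package errors."""


class ValidationError(MixtoxError, ValueError):
    """Malformed, inconsistent or infeasible inputs / configuration."""


class DomainError(MixtoxError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class IdentifiabilityError(MixtoxError, ValueError):
    """Data cannot identify the requested parameters (e.g. flat response)."""


class NumericalError(MixtoxError, RuntimeError):
    """Numerical failure: non-convergence, lost bracket, internal inconsistency."""


class ConvergenceError(NumericalError):
    """Optimizer failed to converge after the multi-start budget."""
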