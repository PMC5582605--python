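"""Exception hierarchy.

Validation problems (bad configuration, malformed input files) and numerical
problems (fits that do not converge, grids that do not resolve the physics)
are kept on separate branches so the command line can map them to distinct
exit codes.
"""


class KdtliError(Exception):
    """Base class for all package errors."""


class ValidationError(KdtliError, ValueError):
    """Invalid user input: configuration, domain violations, file schemas."""


class FormulaError(ValidationError):
    """A sum formula contains an unknown element symbol."""


class ConfigurationError(ValidationError):
    """A required molecular or instrument parameter is missing or invalid."""


class SchemaError(ValidationError):
    """A data file does not match its declared CSV dialect."""


class ComputationError(KdtliError, RuntimeError):
    """Numerical failure: non-convergence, non-identifiability, resolution."""


class ConvergenceError(ComputationError):
    """A Fourier-order cutoff is too small for the requested accuracy."""


class ResolutionError(ComputationError):
    """The wave-propagation grid does not resolve the interference pattern."""


class FitError(ComputationError):
    """A least-squares fit failed or the data cannot constrain the model."""


class IdentifiabilityError(FitError):
    """The data carry no information about the requested parameter."""


class UnwrapError(FitError):
    """Adjacent deflection phases are too far apart to unwrap safely."""


class DeconvolutionError(ComputationError):
    """A chopper sequence is not a maximal-length sequence."""
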