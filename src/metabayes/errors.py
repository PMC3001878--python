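"""Exception hierarchy shared across the package."""


class MetaBayesError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MetaBayesError, ValueError):
    """A precondition on user-supplied input was violated."""


class DegenerateCurvatureError(MetaBayesError):
    """The negative Hessian at the candidate mode is not positive definite.

    Carries the offending (smallest) eigenvalue so callers can report how far
    from a proper maximum the optimizer terminated.
    """

    def __init__(self, eigenvalue: float, message: str | None = None):
        self.eigenvalue = float(eigenvalue)
        super().__init__(
            message
            or f"negative Hessian not positive definite: min eigenvalue {self.eigenvalue:.6g}"
        )


class NumericalPrecisionError(MetaBayesError):
    """A finite-difference step underflowed or a computation lost all precision."""


class InvalidLossError(MetaBayesError):
    """The posterior risk is unbounded below over the action space."""


class UnsupportedDimensionError(MetaBayesError):
    """Quadrature requested for a state dimension beyond the documented limit."""


class CovarianceError(MetaBayesError):
    """A residual covariance is singular or otherwise unusable."""


class IllPosedError(MetaBayesError):
    """The inversion is under-determined; proper priors are required."""


class ConvergenceError(MetaBayesError):
    """No optimizer start produced a usable fit."""


class ConfigError(MetaBayesError):
    """A configuration file or object is invalid."""


class ParseError(MetaBayesError):
    """A trial-data file could not be parsed; names the offending row/column."""
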