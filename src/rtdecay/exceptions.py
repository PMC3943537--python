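"""Exception hierarchy.

Validation failures (bad inputs, malformed files) derive from
:class:`ValidationError`; numerical failures (non-convergence, degenerate
designs) derive from :class:`NumericalError`.  The CLI maps the two branches
to distinct exit codes.
"""


class RTDecayError(Exception):
    """Base class for all rtdecay errors."""


class ValidationError(RTDecayError, ValueError):
    """Invalid user input or inconsistent data."""


class InvalidInputError(ValidationError):
    pass


class InvalidCellError(ValidationError):
    """Unit-cell parameters do not define a positive-definite metric."""


class FormatError(ValidationError):
    """Malformed series file or table."""


class DomainError(ValidationError):
    """Evaluation outside the declared domain of a radial curve."""


class InsufficientDataError(ValidationError):
    """Too few observations to carry out a fit or analysis."""


class NumericalError(RTDecayError, RuntimeError):
    """Numerical failure during fitting or root finding."""


class DegenerateDesignError(NumericalError):
    """Regression design with no usable spread."""


class UnderDeterminedError(NumericalError):
    """More free parameters than observations."""


class NoDecayError(NumericalError):
    """Decay parameters imply no intensity decay (beta = gamma = 0)."""


class ConvergenceError(NumericalError):
    pass
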