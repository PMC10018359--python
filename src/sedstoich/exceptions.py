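"""Exception hierarchy shared across the pipeline."""


class SedstoichError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SedstoichError, ValueError):
    """An argument violates a documented precondition."""


class NumericalFailureError(SedstoichError, ArithmeticError):
    """A computation produced non-finite values or an unstable step."""


class FitFailureError(SedstoichError, RuntimeError):
    """A nonlinear fit did not converge or the model is unidentifiable.

    Carries the best residuals seen, when available, in ``best_residuals``.
    """

    def __init__(self, message: str, best_residuals=None):
        super().__init__(message)
        self.best_residuals = best_residuals


class UndefinedResultError(SedstoichError, ZeroDivisionError):
    """The requested quantity is undefined for this input (e.g. zero area)."""


class UnidentifiableError(SedstoichError, ValueError):
    """A linear system cannot pin down the requested unknowns.

    ``solvable`` lists the unknowns (or groups) that are identifiable.
    """

    def __init__(self, message: str, solvable=()):
        super().__init__(message)
        self.solvable = tuple(solvable)


class ParseError(SedstoichError, ValueError):
    """A data file could not be parsed; message names the offending line."""


class ConfigError(SedstoichError, ValueError):
    """A pipeline configuration failed validation before execution."""
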