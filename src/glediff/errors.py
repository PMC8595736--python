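"""Exception types shared across the package."""

from __future__ import annotations


class GLEDiffError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(GLEDiffError, ValueError):
    """A physical or mathematical parameter is outside its admissible domain."""


class SingularPointError(GLEDiffError, ValueError):
    """Evaluation requested at a point where the function is singular."""


class AccuracyError(GLEDiffError, RuntimeError):
    """A numerical routine could not meet its accuracy target.

    Attributes
    ----------
    where : object
        Offending abscissae (e.g. the time values at which an inverse
        Laplace transform failed its error estimate), when available.
    """

    def __init__(self, message: str, where=None):
        super().__init__(message)
        self.where = where


class CurveParseError(GLEDiffError, ValueError):
    """A curve or trajectory file could not be parsed.

    Attributes
    ----------
    line : int or None
        1-based line number of the offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConvergenceWarning(UserWarning):
    """A stochastic routine finished without meeting its convergence check."""
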