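"""Typed exceptions for invalid parameter regimes.

The analytic results in this package hold only under definite sign and
non-degeneracy conditions (positive payoff differences, non-empty response
cells, non-singular type 2 evidence). Violations raise one of the errors
below rather than returning sentinel values.
"""


class MetacritError(Exception):
    """Base class for all package-specific errors."""


class UndefinedQuotientError(MetacritError, ValueError):
    """A reward quotient (Q1, Q2) has zero or mixed-sign payoff differences,
    so no criterion maximizes expected reward."""


class InvertedRewardError(MetacritError, ValueError):
    """Both payoff differences are negative: the stationary point of the
    expected-reward function is a minimum, not a maximum."""


class DegenerateResponseError(MetacritError, ValueError):
    """A type 1 response has probability zero, so rates conditional on that
    response are undefined."""


class DegenerateModelError(MetacritError, ValueError):
    """The type 2 evidence distribution is degenerate (e.g. complete signal
    loss with no type 2 noise), so joint rates cannot be computed."""


class ZeroSensitivityError(MetacritError, ValueError):
    """d' = 0 makes the requested criterion undefined (division by d') or
    the objective flat."""


class FitError(MetacritError, RuntimeError):
    """Meta-d' estimation failed or the data cannot constrain the fit."""
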