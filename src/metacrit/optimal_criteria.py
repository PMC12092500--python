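"""Closed-form optimal type 1 and type 2 criteria for four objectives.

The four optimization contexts are:

``accuracy``
    maximize the probability that confidence is congruent with type 1
    correctness;
``reward``
    maximize expected type 2 reward under a payoff matrix over the four
    type 2 outcomes, summarized by the quotient Q2;
``calibration``
    report high confidence exactly when the posterior probability of a
    correct type 1 response exceeds a threshold p_correct_T (odds O_T);
``hf``
    maximize the difference between type 2 hit rate and false alarm rate,
    response-specifically.

All unclipped type 2 optima have the form c1_A* + ln(theta)/d' on the "S2"
side and c1_A* - ln(theta)/d' on the "S1" side, where c1_A* =
ln(p_S1/p_S2)/d' is the accuracy-optimal type 1 criterion and theta is 1
(accuracy), Q2 (reward) or O_T (calibration); the hf optima replace the
prior-dependent term with ln(HR1/FAR1) and ln((1-HR1)/(1-FAR1)). Each
optimum is clipped at the actual c1 so the consistency constraint
c2_S1 <= c1 <= c2_S2 holds; flags record when a bound was active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import (
    InvertedRewardError,
    UndefinedQuotientError,
    ZeroSensitivityError,
)
from .sdt_core import (
    CalibrationTarget,
    RewardMatrix1,
    RewardMatrix2,
    SDTParams,
    Type2Criteria,
    type1_summary,
)

__all__ = [
    "OptimalCriteria",
    "BiasRatio",
    "CONTEXTS",
    "c1_opt_accuracy",
    "c1_opt_reward",
    "c1_opt_hf",
    "c2_opt_accuracy",
    "c2_opt_reward",
    "c2_opt_calibration",
    "c2_opt_hf",
    "reward_quotient",
    "confidence_bias_ratio",
]

CONTEXTS = ("accuracy", "reward", "calibration", "hf")


@dataclass(frozen=True)
class OptimalCriteria:
    """Optimal criteria for one context, with constraint-clipping flags.

    ``c1_star`` is None for the calibration context, which prescribes no
    type 1 criterion. ``clipped_S1``/``clipped_S2`` mark that the
    consistency bound at the actual c1 was active, i.e. the reported type 2
    criterion sits at c1 rather than at the interior optimum.
    """

    context: str
    c1_star: float | None
    c2_S1_star: float
    c2_S2_star: float
    clipped_S1: bool
    clipped_S2: bool

    def as_type2_criteria(self) -> Type2Criteria:
        return Type2Criteria(c2_S1=self.c2_S1_star, c2_S2=self.c2_S2_star)


@dataclass(frozen=True)
class BiasRatio:
    """Normalized criterion distances (c2 - c1)/(c2* - c1) per response.

    A ratio below 1 flags over-confidence (the actual criterion is closer
    to c1 than the optimum), above 1 under-confidence, exactly 1 optimal
    placement.
    """

    ratio_S1: float
    ratio_S2: float


def _check_d_prime(d_prime: float) -> None:
    if d_prime < 0:
        raise ValueError(f"d_prime must be >= 0, got {d_prime}")


def _check_quotient(numerator: float, denominator: float, name: str) -> float:
    if numerator < 0 and denominator < 0:
        raise InvertedRewardError(
            f"both payoff differences defining {name} are negative: the "
            "expected-reward function is inverted and its stationary point "
            "is a minimum, not a maximum"
        )
    if numerator <= 0 or denominator <= 0:
        raise UndefinedQuotientError(
            f"{name} is undefined: payoff differences must both be strictly "
            f"positive, got numerator={numerator}, denominator={denominator}"
        )
    return numerator / denominator


def reward_quotient(obj) -> float:
    """Validated quotient for a payoff matrix or calibration target.

    Returns Q1 for a :class:`RewardMatrix1`, Q2 for a
    :class:`RewardMatrix2` (raising on zero/mixed-sign or both-negative
    payoff differences), and O_T for a :class:`CalibrationTarget`.
    """
    if isinstance(obj, RewardMatrix1):
        return _check_quotient(obj.numerator, obj.denominator, "Q1")
    if isinstance(obj, RewardMatrix2):
        return _check_quotient(obj.numerator, obj.denominator, "Q2")
    if isinstance(obj, CalibrationTarget):
        return obj.O_T
    raise TypeError(f"unsupported quotient source: {type(obj).__name__}")


# ---------------------------------------------------------------------------
# type 1 optima
# ---------------------------------------------------------------------------

def c1_opt_accuracy(d_prime: float, p_S2: float) -> float:
    """Accuracy-maximizing type 1 criterion, ln(p_S1/p_S2)/d'.

    At d' = 0 with equal priors the accuracy surface is flat and the
    conventional value 0 is returned; with unequal priors the optimum is a
    signed infinity (always give the more probable response).
    """
    _check_d_prime(d_prime)
    if not 0.0 < p_S2 < 1.0:
        raise ValueError(f"p_S2 must lie in (0, 1), got {p_S2}")
    log_prior_ratio = math.log((1.0 - p_S2) / p_S2)
    if d_prime == 0.0:
        if log_prior_ratio == 0.0:
            return 0.0
        return math.copysign(math.inf, log_prior_ratio)
    return log_prior_ratio / d_prime


def c1_opt_reward(d_prime: float, p_S2: float, rm: RewardMatrix1) -> float:
    """Reward-maximizing type 1 criterion, [ln(p_S1/p_S2) + ln Q1]/d'."""
    _check_d_prime(d_prime)
    q1 = reward_quotient(rm)
    if d_prime == 0.0:
        arg = math.log((1.0 - p_S2) / p_S2) + math.log(q1)
        if arg == 0.0:
            return 0.0
        return math.copysign(math.inf, arg)
    return c1_opt_accuracy(d_prime, p_S2) + math.log(q1) / d_prime


def c1_opt_hf() -> float:
    """Criterion maximizing HR1 - FAR1: always 0, independent of d' and
    priors (at d' = 0 the objective is identically 0 and the conventional
    value 0 is returned)."""
    return 0.0


# ---------------------------------------------------------------------------
# type 2 optima
# ---------------------------------------------------------------------------

def _clip_pair(center_S1: float, center_S2: float, c1: float, context: str,
               c1_star: float | None) -> OptimalCriteria:
    c2_s1 = min(center_S1, c1)
    c2_s2 = max(center_S2, c1)
    return OptimalCriteria(
        context=context,
        c1_star=c1_star,
        c2_S1_star=c2_s1,
        c2_S2_star=c2_s2,
        clipped_S1=center_S1 > c1,
        clipped_S2=center_S2 < c1,
    )


def c2_opt_accuracy(params: SDTParams) -> OptimalCriteria:
    """Type 2 criteria maximizing type 2 accuracy.

    c2_S2* = max(c1_A*, c1) and c2_S1* = min(c1_A*, c1): both sit as close
    to the accuracy-optimal type 1 criterion as the consistency constraints
    allow. When c1 = c1_A* both equal c1 and the observer never reports low
    confidence.
    """
    if params.d_prime == 0.0 and params.p_S2 != 0.5:
        raise ZeroSensitivityError(
            "c2_opt_accuracy undefined at d' = 0 with unequal priors"
        )
    c1a = c1_opt_accuracy(params.d_prime, params.p_S2)
    return _clip_pair(c1a, c1a, params.c1, "accuracy", c1a)


def c2_opt_reward(params: SDTParams, rm: RewardMatrix2) -> OptimalCriteria:
    """Type 2 criteria maximizing expected type 2 reward.

    c2_S2* = max(c1_A* + ln(Q2)/d', c1), c2_S1* = min(c1_A* - ln(Q2)/d', c1):
    symmetric about c1_A* with offset ln(Q2)/d', clipped at c1.
    """
    q2 = reward_quotient(rm)
    if params.d_prime == 0.0:
        raise ZeroSensitivityError(
            "c2_opt_reward undefined at d' = 0 (offset ln(Q2)/d' diverges)"
        )
    c1a = c1_opt_accuracy(params.d_prime, params.p_S2)
    off = math.log(q2) / params.d_prime
    return _clip_pair(c1a - off, c1a + off, params.c1, "reward", None)


def c2_opt_calibration(
    params: SDTParams, target: CalibrationTarget
) -> OptimalCriteria:
    """Type 2 criteria calibrating high confidence to a threshold accuracy.

    c2_S2* = max(c1_A* + ln(O_T)/d', c1) and the mirror image for "S1"
    responses. At an unclipped optimum, p(correct1 | x = c2*) equals
    p_correct_T exactly. Formally identical to the reward optimum with
    Q2 = O_T. The calibration context prescribes no type 1 criterion.
    """
    if params.d_prime == 0.0:
        raise ZeroSensitivityError(
            "c2_opt_calibration undefined at d' = 0 (offset ln(O_T)/d' "
            "diverges)"
        )
    c1a = c1_opt_accuracy(params.d_prime, params.p_S2)
    off = math.log(target.O_T) / params.d_prime
    return _clip_pair(c1a - off, c1a + off, params.c1, "calibration", None)


def c2_opt_hf(
    params: SDTParams,
    hr1: float | None = None,
    far1: float | None = None,
) -> OptimalCriteria:
    """Type 2 criteria maximizing response-specific HR2 - FAR2.

    c2_S2* = max(ln(HR1/FAR1)/d', c1) and
    c2_S1* = min(ln((1-HR1)/(1-FAR1))/d', c1). By default HR1/FAR1 are the
    model-implied rates from (d', c1); externally measured rates may be
    supplied instead (both together), in which case they are used verbatim.
    For d' > 0 the unclipped optima are strictly positive ("S2") and
    strictly negative ("S1").
    """
    if params.d_prime == 0.0:
        raise ZeroSensitivityError(
            "c2_opt_hf undefined at d' = 0: HR2 - FAR2 is identically 0"
        )
    if (hr1 is None) != (far1 is None):
        raise ValueError("supply both hr1 and far1, or neither")
    if hr1 is None:
        t1 = type1_summary(params)
        hr1, far1 = t1.HR1, t1.FAR1
    if not (0.0 < far1 < hr1 < 1.0):
        raise ValueError(
            f"require 0 < FAR1 < HR1 < 1, got HR1={hr1}, FAR1={far1}"
        )
    d = params.d_prime
    center_S2 = math.log(hr1 / far1) / d
    center_S1 = math.log((1.0 - hr1) / (1.0 - far1)) / d
    return _clip_pair(center_S1, center_S2, params.c1, "hf", c1_opt_hf())


# ---------------------------------------------------------------------------
# over-/under-confidence
# ---------------------------------------------------------------------------

def confidence_bias_ratio(
    c1: float, actual: Type2Criteria, optimal: OptimalCriteria
) -> BiasRatio:
    """Actual-to-optimal normalized criterion distances.

    ratio = (c2 - c1)/(c2* - c1) per response. Undefined when the optimal
    criterion coincides with c1 (clipped or degenerate optimum).
    """
    actual.validate_against(c1)
    d_s1 = optimal.c2_S1_star - c1
    d_s2 = optimal.c2_S2_star - c1
    if d_s1 == 0.0 or d_s2 == 0.0:
        raise ZeroDivisionError(
            "bias ratio undefined: optimal type 2 criterion equals c1 "
            f"(c2_S1*-c1={d_s1}, c2_S2*-c1={d_s2})"
        )
    return BiasRatio(
        ratio_S1=(actual.c2_S1 - c1) / d_s1,
        ratio_S2=(actual.c2_S2 - c1) / d_s2,
    )
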