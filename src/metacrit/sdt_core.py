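"""Equal-variance signal detection forward model for binary confidence.

Coordinate convention (used package-wide): evidence x for an S1 stimulus is
distributed Normal(-d'/2, 1) and for an S2 stimulus Normal(+d'/2, 1). With
this placement the likelihood ratio of S2 to S1 at a point x is exactly
exp(x * d'), so a criterion c corresponds to the likelihood-ratio criterion
beta = exp(c * d').

The observer responds "S2" when x > c1 and "S1" otherwise (ties at x = c1 go
to "S1"; the event has measure zero under the continuous model but the
tie-break is fixed so that discretized inputs are reproducible). Confidence
is "high" for an "S2" response when x > c2_S2 and for an "S1" response when
x < c2_S1, with the consistency constraint c2_S1 <= c1 <= c2_S2.

All rates are computed with the complementary normal CDF where the mass is
an upper tail, so that values remain accurate for criteria many standard
deviations from the means. Criteria may be +/-inf to express always/never
policies; the rate formulas take the corresponding limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_expit, ndtr

from .errors import DegenerateResponseError

__all__ = [
    "SDTParams",
    "Type2Criteria",
    "Type1Summary",
    "Type2Summary",
    "RewardMatrix1",
    "RewardMatrix2",
    "CalibrationTarget",
    "Reward2Summary",
    "type1_summary",
    "p_correct_given_x",
    "type2_summary",
    "expected_reward1",
    "expected_reward2",
    "type1_roc",
    "type2_roc",
]


def _Phi(z):
    """Standard normal CDF, vectorized, exact at +/-inf."""
    return ndtr(z)


def _Phi_c(z):
    """Standard normal survival function via the complementary CDF."""
    return ndtr(-np.asarray(z, dtype=float))


@dataclass(frozen=True)
class SDTParams:
    """Type 1 generative world: sensitivity, criterion and stimulus prior.

    Parameters
    ----------
    d_prime : float
        Separation of the S1 and S2 evidence distributions in SD units
        (>= 0).
    c1 : float
        Type 1 criterion on the decision axis; the observer responds "S2"
        for x > c1. May be +/-inf.
    p_S2 : float
        Prior probability of an S2 stimulus, strictly between 0 and 1.
    """

    d_prime: float
    c1: float = 0.0
    p_S2: float = 0.5

    def __post_init__(self):
        if not self.d_prime >= 0:
            raise ValueError(f"d_prime must be >= 0, got {self.d_prime}")
        if not 0.0 < self.p_S2 < 1.0:
            raise ValueError(f"p_S2 must lie in (0, 1), got {self.p_S2}")
        if np.isnan(self.c1):
            raise ValueError("c1 must not be NaN")

    @property
    def p_S1(self) -> float:
        return 1.0 - self.p_S2

    @property
    def mu_S1(self) -> float:
        """Mean of the S1 evidence distribution."""
        return -self.d_prime / 2.0

    @property
    def mu_S2(self) -> float:
        """Mean of the S2 evidence distribution."""
        return self.d_prime / 2.0


@dataclass(frozen=True)
class Type2Criteria:
    """Response-specific confidence criteria.

    ``c2_S1`` bounds high confidence for "S1" responses (high iff x < c2_S1)
    and ``c2_S2`` for "S2" responses (high iff x > c2_S2). Validity relative
    to a type 1 criterion (c2_S1 <= c1 <= c2_S2) is checked by
    :func:`Type2Criteria.validate_against`.
    """

    c2_S1: float
    c2_S2: float

    def __post_init__(self):
        if np.isnan(self.c2_S1) or np.isnan(self.c2_S2):
            raise ValueError("type 2 criteria must not be NaN")

    def validate_against(self, c1: float) -> None:
        if not (self.c2_S1 <= c1 <= self.c2_S2):
            raise ValueError(
                "consistency constraint violated: require "
                f"c2_S1 <= c1 <= c2_S2, got c2_S1={self.c2_S1}, c1={c1}, "
                f"c2_S2={self.c2_S2}"
            )


@dataclass(frozen=True)
class Type1Summary:
    """Type 1 rates implied by (d', c1, p_S2)."""

    HR1: float
    FAR1: float
    p_correct1: float
    beta1: float
    p_resp_S2: float
    p_resp_S1: float


@dataclass(frozen=True)
class Type2Summary:
    """Type 2 (confidence) rates implied by the model.

    Response-specific type 2 hit/false-alarm rates condition on the type 1
    response; overall rates condition only on type 1 correctness. ``D2``
    fields are hit rate minus false alarm rate. ``p_high*`` fields give the
    probability of a high-confidence report (overall and conditional on each
    response), which the model treats as the binary analogue of average
    confidence.
    """

    HR2_S2: float
    FAR2_S2: float
    HR2_S1: float
    FAR2_S1: float
    HR2: float
    FAR2: float
    p_correct2: float
    p_correct2_S1: float
    p_correct2_S2: float
    D2: float
    D2_S1: float
    D2_S2: float
    p_high: float
    p_high_S1: float
    p_high_S2: float


@dataclass(frozen=True)
class RewardMatrix1:
    """Payoffs for the four type 1 outcomes (points; any real)."""

    R_hit1: float
    R_miss1: float
    R_CR1: float
    R_FA1: float

    @property
    def numerator(self) -> float:
        return self.R_CR1 - self.R_FA1

    @property
    def denominator(self) -> float:
        return self.R_hit1 - self.R_miss1

    @property
    def Q1(self) -> float:
        """Relative reward quotient (R_CR1 - R_FA1)/(R_hit1 - R_miss1).

        Only meaningful when both differences are strictly positive; sign
        checks are enforced where Q1 is consumed (see
        :mod:`metacrit.optimal_criteria`).
        """
        return self.numerator / self.denominator


@dataclass(frozen=True)
class RewardMatrix2:
    """Payoffs for the four type 2 outcomes.

    Type 2 hits are high-confidence corrects, type 2 correct rejections are
    low-confidence errors, type 2 misses are low-confidence corrects and
    type 2 false alarms are high-confidence errors.
    """

    R_hit2: float
    R_miss2: float
    R_CR2: float
    R_FA2: float

    @classmethod
    def from_quotient(cls, q2: float) -> "RewardMatrix2":
        """Canonical matrix (1, 0, q2, 0) realizing a given quotient Q2."""
        return cls(R_hit2=1.0, R_miss2=0.0, R_CR2=float(q2), R_FA2=0.0)

    @property
    def numerator(self) -> float:
        return self.R_CR2 - self.R_FA2

    @property
    def denominator(self) -> float:
        return self.R_hit2 - self.R_miss2

    @property
    def Q2(self) -> float:
        """Relative reward quotient (R_CR2 - R_FA2)/(R_hit2 - R_miss2)."""
        return self.numerator / self.denominator


@dataclass(frozen=True)
class CalibrationTarget:
    """Threshold type 1 accuracy for reporting high confidence."""

    p_correct_T: float

    def __post_init__(self):
        if not 0.0 < self.p_correct_T < 1.0:
            raise ValueError(
                f"p_correct_T must lie in (0, 1), got {self.p_correct_T}"
            )

    @property
    def O_T(self) -> float:
        """Odds of a correct response at the threshold accuracy."""
        return self.p_correct_T / (1.0 - self.p_correct_T)


@dataclass(frozen=True)
class Reward2Summary:
    """Expected type 2 reward, conditional on each response and overall."""

    E_S1: float
    E_S2: float
    overall: float


# ---------------------------------------------------------------------------
# type 1
# ---------------------------------------------------------------------------

def type1_summary(params: SDTParams) -> Type1Summary:
    """Type 1 hit/false-alarm rates, accuracy and likelihood-ratio criterion.

    HR1 = 1 - Phi(c1 - d'/2), FAR1 = 1 - Phi(c1 + d'/2),
    p(correct1) = p(S2) HR1 + p(S1) (1 - FAR1), beta1 = exp(c1 d').
    """
    d, c1 = params.d_prime, params.c1
    hr1 = float(_Phi_c(c1 - d / 2.0))
    far1 = float(_Phi_c(c1 + d / 2.0))
    p_correct1 = params.p_S2 * hr1 + params.p_S1 * (1.0 - far1)
    with np.errstate(over="ignore"):
        beta1 = float(np.exp(c1 * d))
    p_resp_S2 = params.p_S2 * hr1 + params.p_S1 * far1
    return Type1Summary(
        HR1=hr1,
        FAR1=far1,
        p_correct1=p_correct1,
        beta1=beta1,
        p_resp_S2=p_resp_S2,
        p_resp_S1=1.0 - p_resp_S2,
    )


def posterior_p_S2(params: SDTParams, x):
    """Posterior probability p(S2 | x).

    The posterior log-odds for S2 are x*d' + ln(p_S2/p_S1); the computation
    stays in log space so extreme x do not overflow.
    """
    x = np.asarray(x, dtype=float)
    log_prior_odds = np.log(params.p_S2) - np.log(params.p_S1)
    return np.exp(log_expit(x * params.d_prime + log_prior_odds))


def p_correct_given_x(params: SDTParams, x):
    """Probability that the response dictated by c1 at evidence x is correct.

    For x > c1 the response is "S2" and the value is p(S2|x); for x <= c1
    it is p(S1|x). Vectorized in ``x``.
    """
    x = np.asarray(x, dtype=float)
    p_s2 = posterior_p_S2(params, x)
    out = np.where(x > params.c1, p_s2, 1.0 - p_s2)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# type 2
# ---------------------------------------------------------------------------

def _high_conf_masses(params: SDTParams, crit: Type2Criteria):
    """Joint masses p(response region & high confidence | stimulus).

    Returns (lo_S1, lo_S2, hi_S1, hi_S2): the probability of landing below
    c2_S1 (high-confidence "S1") and above c2_S2 (high-confidence "S2"),
    conditional on each stimulus.
    """
    lo_S1 = float(_Phi(crit.c2_S1 - params.mu_S1))
    lo_S2 = float(_Phi(crit.c2_S1 - params.mu_S2))
    hi_S1 = float(_Phi_c(crit.c2_S2 - params.mu_S1))
    hi_S2 = float(_Phi_c(crit.c2_S2 - params.mu_S2))
    return lo_S1, lo_S2, hi_S1, hi_S2


def _ratio(num: float, den: float, what: str) -> float:
    if den <= 0.0:
        raise DegenerateResponseError(
            f"{what} is undefined: conditioning event has probability 0"
        )
    return num / den


def type2_summary(params: SDTParams, crit: Type2Criteria) -> Type2Summary:
    """Response-specific and overall type 2 rates under the standard model.

    Response-specific rates are truncated-normal mass ratios, e.g.
    HR2_S2 = [1 - Phi(c2_S2 - d'/2)] / [1 - Phi(c1 - d'/2)]. Overall HR2 and
    FAR2 condition high confidence on type 1 correctness, weighting the
    stimulus-conditional masses by the priors.
    """
    crit.validate_against(params.c1)
    d, c1 = params.d_prime, params.c1
    p_S1, p_S2 = params.p_S1, params.p_S2
    t1 = type1_summary(params)

    # stimulus-conditional response-region masses
    p_s2resp_S2 = t1.HR1             # p(x > c1 | S2): correct "S2"
    p_s2resp_S1 = t1.FAR1            # p(x > c1 | S1): incorrect "S2"
    p_s1resp_S1 = 1.0 - t1.FAR1      # p(x < c1 | S1): correct "S1"
    p_s1resp_S2 = 1.0 - t1.HR1       # p(x < c1 | S2): incorrect "S1"

    lo_S1, lo_S2, hi_S1, hi_S2 = _high_conf_masses(params, crit)

    hr2_s2 = _ratio(hi_S2, p_s2resp_S2, 'HR2,"S2"')
    far2_s2 = _ratio(hi_S1, p_s2resp_S1, 'FAR2,"S2"')
    hr2_s1 = _ratio(lo_S1, p_s1resp_S1, 'HR2,"S1"')
    far2_s1 = _ratio(lo_S2, p_s1resp_S2, 'FAR2,"S1"')

    # overall rates: high confidence conditional on type 1 correctness
    p_high_correct = p_S2 * hi_S2 + p_S1 * lo_S1
    p_high_incorrect = p_S1 * hi_S1 + p_S2 * lo_S2
    p_correct1 = t1.p_correct1
    hr2 = _ratio(p_high_correct, p_correct1, "HR2")
    far2 = _ratio(p_high_incorrect, 1.0 - p_correct1, "FAR2")

    p_correct2 = p_correct1 * hr2 + (1.0 - p_correct1) * (1.0 - far2)

    # response-conditional type 1 accuracies weight the response-specific
    # type 2 accuracies
    p_resp_S2 = t1.p_resp_S2
    p_resp_S1 = t1.p_resp_S1
    p_corr1_g_s2 = _ratio(p_S2 * p_s2resp_S2, p_resp_S2, 'p(correct1|"S2")')
    p_corr1_g_s1 = _ratio(p_S1 * p_s1resp_S1, p_resp_S1, 'p(correct1|"S1")')
    p_correct2_s2 = p_corr1_g_s2 * hr2_s2 + (1.0 - p_corr1_g_s2) * (1.0 - far2_s2)
    p_correct2_s1 = p_corr1_g_s1 * hr2_s1 + (1.0 - p_corr1_g_s1) * (1.0 - far2_s1)

    p_high = p_S1 * (lo_S1 + hi_S1) + p_S2 * (lo_S2 + hi_S2)
    p_high_s1 = _ratio(p_S1 * lo_S1 + p_S2 * lo_S2, p_resp_S1, 'p(high|"S1")')
    p_high_s2 = _ratio(p_S1 * hi_S1 + p_S2 * hi_S2, p_resp_S2, 'p(high|"S2")')

    return Type2Summary(
        HR2_S2=hr2_s2,
        FAR2_S2=far2_s2,
        HR2_S1=hr2_s1,
        FAR2_S1=far2_s1,
        HR2=hr2,
        FAR2=far2,
        p_correct2=p_correct2,
        p_correct2_S1=p_correct2_s1,
        p_correct2_S2=p_correct2_s2,
        D2=hr2 - far2,
        D2_S1=hr2_s1 - far2_s1,
        D2_S2=hr2_s2 - far2_s2,
        p_high=p_high,
        p_high_S1=p_high_s1,
        p_high_S2=p_high_s2,
    )


# ---------------------------------------------------------------------------
# expected reward
# ---------------------------------------------------------------------------

def expected_reward1(params: SDTParams, rm: RewardMatrix1) -> float:
    """Expected type 1 reward.

    E(reward1) = p(S2)[R_hit1 HR1 + R_miss1 (1 - HR1)]
               + p(S1)[R_CR1 (1 - FAR1) + R_FA1 FAR1].
    """
    t1 = type1_summary(params)
    return params.p_S2 * (rm.R_hit1 * t1.HR1 + rm.R_miss1 * (1.0 - t1.HR1)) + (
        params.p_S1 * (rm.R_CR1 * (1.0 - t1.FAR1) + rm.R_FA1 * t1.FAR1)
    )


def expected_reward2(
    params: SDTParams, crit: Type2Criteria, rm: RewardMatrix2
) -> Reward2Summary:
    """Expected type 2 reward conditional on each response, and overall.

    For "S2" responses the four joint outcomes are (hit1, low conf),
    (hit1, high conf), (FA1, low conf) and (FA1, high conf), with masses
    normalized by p(response = "S2"); payoffs follow the type 2 outcome of
    each cell (a low-confidence error is a type 2 correct rejection, etc.).
    The overall value weights the conditional expectations by the response
    probabilities.
    """
    crit.validate_against(params.c1)
    p_S1, p_S2 = params.p_S1, params.p_S2
    t1 = type1_summary(params)
    lo_S1, lo_S2, hi_S1, hi_S2 = _high_conf_masses(params, crit)

    # "S2" responses: stimulus-conditional masses in (c1, c2_S2] and (c2_S2, inf)
    hit_hc = p_S2 * hi_S2
    hit_lc = p_S2 * (t1.HR1 - hi_S2)
    fa_hc = p_S1 * hi_S1
    fa_lc = p_S1 * (t1.FAR1 - hi_S1)
    p_resp_s2 = t1.p_resp_S2
    if p_resp_s2 <= 0.0:
        raise DegenerateResponseError(
            'E(reward2,"S2") undefined: p(response="S2") = 0'
        )
    e_s2 = (
        hit_lc * rm.R_miss2
        + hit_hc * rm.R_hit2
        + fa_lc * rm.R_CR2
        + fa_hc * rm.R_FA2
    ) / p_resp_s2

    # "S1" responses: CR1 (stimulus S1) and miss1 (stimulus S2)
    cr_hc = p_S1 * lo_S1
    cr_lc = p_S1 * (1.0 - t1.FAR1 - lo_S1)
    miss_hc = p_S2 * lo_S2
    miss_lc = p_S2 * (1.0 - t1.HR1 - lo_S2)
    p_resp_s1 = t1.p_resp_S1
    if p_resp_s1 <= 0.0:
        raise DegenerateResponseError(
            'E(reward2,"S1") undefined: p(response="S1") = 0'
        )
    e_s1 = (
        cr_lc * rm.R_miss2
        + cr_hc * rm.R_hit2
        + miss_lc * rm.R_CR2
        + miss_hc * rm.R_FA2
    ) / p_resp_s1

    overall = p_resp_s1 * e_s1 + p_resp_s2 * e_s2
    return Reward2Summary(E_S1=e_s1, E_S2=e_s2, overall=overall)


# ---------------------------------------------------------------------------
# ROC curves
# ---------------------------------------------------------------------------

def type1_roc(params: SDTParams, c1_grid) -> np.ndarray:
    """Type 1 ROC points (FAR1, HR1) from sweeping the type 1 criterion.

    Returns an array of shape (len(grid), 2). The grid must be strictly
    increasing; points move from (1, 1) toward (0, 0) as the criterion
    becomes more conservative.
    """
    grid = np.asarray(c1_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("criteria grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("criteria grid must be strictly increasing")
    d = params.d_prime
    hr = _Phi_c(grid - d / 2.0)
    far = _Phi_c(grid + d / 2.0)
    return np.column_stack([far, hr])


def type2_roc(params: SDTParams, response: str, c2_grid) -> np.ndarray:
    """Response-specific type 2 ROC points (FAR2, HR2) from sweeping c2.

    For "S2" responses the grid must lie at or above c1; for "S1" responses
    at or below c1.
    """
    grid = np.asarray(c2_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("criteria grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("criteria grid must be strictly increasing")
    d, c1 = params.d_prime, params.c1
    t1 = type1_summary(params)
    if response == "S2":
        if np.any(grid < c1):
            raise ValueError('c2 grid for "S2" responses must satisfy c2 >= c1')
        num_hr = _Phi_c(grid - d / 2.0)
        num_far = _Phi_c(grid + d / 2.0)
        hr = np.array([_ratio(v, t1.HR1, 'HR2,"S2"') for v in num_hr])
        far = np.array([_ratio(v, t1.FAR1, 'FAR2,"S2"') for v in num_far])
    elif response == "S1":
        if np.any(grid > c1):
            raise ValueError('c2 grid for "S1" responses must satisfy c2 <= c1')
        num_hr = _Phi(grid + d / 2.0)
        num_far = _Phi(grid - d / 2.0)
        hr = np.array(
            [_ratio(v, 1.0 - t1.FAR1, 'HR2,"S1"') for v in num_hr]
        )
        far = np.array(
            [_ratio(v, 1.0 - t1.HR1, 'FAR2,"S1"') for v in num_far]
        )
    else:
        raise ValueError(f'response must be "S1" or "S2", got {response!r}')
    return np.column_stack([far, hr])
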