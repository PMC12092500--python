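"""Generative models in which type 2 evidence differs from type 1 evidence.

Two mechanisms degrade the evidence available to confidence relative to the
evidence used for the type 1 decision:

type 2 noise
    x2 = x1 + eps, eps ~ N(0, sigma2^2): independent Gaussian noise is
    added before the confidence judgment;
type 2 signal loss
    x2 = (1 - k) x1 + eps: the signal is attenuated by a factor (1 - k)
    and additionally corrupted by type 2 noise.

With sigma2 = 0 and k = 0 both reduce to the standard model (x2 = x1). Per
stimulus, (x1, x2) are jointly normal with mean (mu, (1-k) mu), variances
(1, (1-k)^2 + sigma2^2) and covariance (1-k), so every confidence cell is a
bivariate-normal orthant mass. These masses are computed here by 1-D
Gauss-Legendre quadrature of the conditional normal tail, which vectorizes
over criterion grids; an independent cross-check against
scipy.stats.multivariate_normal lives in the test-suite.

Confidence rule under process models: the response-specific type 2
criterion is compared against x2 even when x2 falls on the far side of c1
from the response. A trial with response "S2" and x2 < c2_S2 is simply low
confidence; no re-evaluation of the type 1 response takes place.

Closed-form optima are not available for these models, so optimal type 2
criteria are found by evaluating the outcome objective on a criterion grid
(exactly, or by Monte-Carlo with common random numbers across grid points)
and taking the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DegenerateModelError, DegenerateResponseError
from .optimal_criteria import (
    OptimalCriteria,
    c2_opt_accuracy,
    c2_opt_calibration,
    c2_opt_hf,
    c2_opt_reward,
)
from .outcome_oracle import OutcomeCurve, argmax_c2, default_grid
from .sdt_core import (
    CalibrationTarget,
    RewardMatrix2,
    SDTParams,
    Type2Criteria,
    Type2Summary,
    type1_summary,
)

__all__ = [
    "ProcessModelParams",
    "simulate_trials",
    "cell_probabilities",
    "joint_type2_rates_exact",
    "model_outcome_curve",
    "optimize_c2_under_model",
    "cost_of_ignoring_suboptimality",
    "sweep_parameter",
]

DEFAULT_LOSS_SIGMA2 = 0.1  # small constant type 2 noise in the loss model
_QUAD_NODES = 240
_QUAD_SPAN = 9.5  # integrate the evidence density out to this many SD


@dataclass(frozen=True)
class ProcessModelParams:
    """Type 2 process model: none, added noise, or signal loss.

    ``model`` is one of {"standard", "noise", "loss"}; ``sigma2`` is the SD
    of the additional type 2 noise (>= 0) and ``k`` the signal-loss
    fraction in [0, 1]. The standard model is exactly sigma2 = 0, k = 0;
    the noise model fixes k = 0. Complete signal loss with no type 2 noise
    (k = 1, sigma2 = 0) makes x2 deterministic and is rejected.
    """

    model: str = "standard"
    sigma2: float = 0.0
    k: float = 0.0

    def __post_init__(self):
        if self.model not in ("standard", "noise", "loss"):
            raise ValueError(f"unknown process model {self.model!r}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError(f"k must lie in [0, 1], got {self.k}")
        if self.model == "standard" and (self.sigma2 != 0 or self.k != 0):
            raise ValueError("standard model requires sigma2 = 0 and k = 0")
        if self.model == "noise" and self.k != 0:
            raise ValueError("noise model fixes k = 0")
        if self.k == 1.0 and self.sigma2 == 0.0:
            raise DegenerateModelError(
                "k = 1 with sigma2 = 0 makes x2 deterministic at 0"
            )
        if self.sigma2 == 0.0 and self.k == 0.0 and self.model != "standard":
            # canonical label for the reduction case
            object.__setattr__(self, "model", "standard")

    @classmethod
    def standard(cls) -> "ProcessModelParams":
        return cls("standard", 0.0, 0.0)

    @classmethod
    def noise(cls, sigma2: float) -> "ProcessModelParams":
        model = "noise" if sigma2 > 0 else "standard"
        return cls(model, float(sigma2), 0.0)

    @classmethod
    def loss(cls, k: float, sigma2: float = DEFAULT_LOSS_SIGMA2) -> "ProcessModelParams":
        if k == 0 and sigma2 == 0:
            return cls.standard()
        return cls("loss", float(sigma2), float(k))

    @property
    def is_standard(self) -> bool:
        return self.sigma2 == 0.0 and self.k == 0.0


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    pm: ProcessModelParams,
    params: SDTParams,
    crit: Type2Criteria,
    n: int,
    seed,
) -> pd.DataFrame:
    """Simulate n i.i.d. trials of the type 1 + type 2 task.

    Stimulus ~ Bernoulli(p_S2); x1 ~ Normal(+/-d'/2, 1); x2 = (1-k) x1 +
    eps with eps ~ N(0, sigma2^2); response "S2" iff x1 > c1; confidence
    high iff (response "S2" and x2 > c2_S2) or (response "S1" and
    x2 < c2_S1). ``seed`` may be an int or a numpy Generator. Returns a
    DataFrame with columns stimulus, x1, x2, response, confidence, correct;
    generating parameters are stored in ``df.attrs``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    crit.validate_against(params.c1)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    is_s2 = rng.random(n) < params.p_S2
    mu = np.where(is_s2, params.mu_S2, params.mu_S1)
    x1 = mu + rng.standard_normal(n)
    # noise draw is unconditional so that the same seed yields common random
    # numbers across sigma2 values
    x2 = (1.0 - pm.k) * x1 + pm.sigma2 * rng.standard_normal(n)

    resp_s2 = x1 > params.c1
    high = np.where(resp_s2, x2 > crit.c2_S2, x2 < crit.c2_S1)
    correct = resp_s2 == is_s2

    df = pd.DataFrame(
        {
            "stimulus": np.where(is_s2, "S2", "S1"),
            "x1": x1,
            "x2": x2,
            "response": np.where(resp_s2, "S2", "S1"),
            "confidence": np.where(high, "high", "low"),
            "correct": correct,
        }
    )
    df.attrs.update(
        model=pm.model,
        sigma2=pm.sigma2,
        k=pm.k,
        d_prime=params.d_prime,
        c1=params.c1,
        p_S2=params.p_S2,
        c2_S1=crit.c2_S1,
        c2_S2=crit.c2_S2,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        n=n,
    )
    return df


# ---------------------------------------------------------------------------
# exact orthant masses
# ---------------------------------------------------------------------------

def _gl_nodes(a: float, b: float, n: int = _QUAD_NODES):
    x, w = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (b - a)
    return a + half * (x + 1.0), half * w


def _phi(z):
    return np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)


def _mass_upper(mu: float, c1: float, c2, k: float, sigma2: float):
    """P(x1 > c1, x2 > c2) for x1 ~ N(mu, 1), x2 = (1-k) x1 + eps.

    Vectorized over c2 (scalar or 1-D array). For sigma2 = 0 (k < 1) the
    event is {x1 > max(c1, c2/(1-k))} and a closed form is used.
    """
    c2 = np.asarray(c2, dtype=float)
    scale = 1.0 - k
    if sigma2 == 0.0:
        if scale <= 0.0:
            raise DegenerateModelError("k = 1 with sigma2 = 0 is degenerate")
        return ndtr(-(np.maximum(c1, c2 / scale) - mu))
    hi = max(c1, mu + _QUAD_SPAN)
    if hi <= c1:
        return np.zeros_like(c2)
    x, w = _gl_nodes(c1, hi)
    tail = ndtr(-(c2[..., None] - scale * x) / sigma2)
    return np.einsum("...j,j->...", tail * _phi(x - mu), w)


def _mass_lower(mu: float, c1: float, c2, k: float, sigma2: float):
    """P(x1 < c1, x2 < c2), the mirror image of :func:`_mass_upper`."""
    c2 = np.asarray(c2, dtype=float)
    scale = 1.0 - k
    if sigma2 == 0.0:
        if scale <= 0.0:
            raise DegenerateModelError("k = 1 with sigma2 = 0 is degenerate")
        return ndtr(np.minimum(c1, c2 / scale) - mu)
    lo = min(c1, mu - _QUAD_SPAN)
    if lo >= c1:
        return np.zeros_like(c2)
    x, w = _gl_nodes(lo, c1)
    tail = ndtr((c2[..., None] - scale * x) / sigma2)
    return np.einsum("...j,j->...", tail * _phi(x - mu), w)


def cell_probabilities(
    pm: ProcessModelParams, params: SDTParams, crit: Type2Criteria
) -> dict[tuple[str, str, str], float]:
    """Joint probabilities p(stimulus, response, confidence) for all 8 cells.

    Keys are (stimulus, response, confidence) with values summing to 1.
    """
    crit.validate_against(params.c1)
    c1 = params.c1
    out: dict[tuple[str, str, str], float] = {}
    for stim, mu, prior in (
        ("S1", params.mu_S1, params.p_S1),
        ("S2", params.mu_S2, params.p_S2),
    ):
        p_resp_s2 = float(ndtr(-(c1 - mu)))
        p_resp_s1 = float(ndtr(c1 - mu))
        hi_s2 = float(_mass_upper(mu, c1, crit.c2_S2, pm.k, pm.sigma2))
        hi_s1 = float(_mass_lower(mu, c1, crit.c2_S1, pm.k, pm.sigma2))
        out[(stim, "S2", "high")] = prior * hi_s2
        out[(stim, "S2", "low")] = prior * max(p_resp_s2 - hi_s2, 0.0)
        out[(stim, "S1", "high")] = prior * hi_s1
        out[(stim, "S1", "low")] = prior * max(p_resp_s1 - hi_s1, 0.0)
    return out


def joint_type2_rates_exact(
    pm: ProcessModelParams, params: SDTParams, crit: Type2Criteria
) -> Type2Summary:
    """Type 2 summary under a process model, from exact orthant masses.

    At sigma2 = 0, k = 0 this equals :func:`metacrit.sdt_core.type2_summary`
    exactly (x2 = x1). Raises :class:`DegenerateModelError` for k = 1 with
    sigma2 = 0.
    """
    cells = cell_probabilities(pm, params, crit)

    def cell(stim, resp, conf):
        return cells[(stim, resp, conf)]

    def resp_mass(resp):
        return sum(cell(s, resp, c) for s in ("S1", "S2") for c in ("low", "high"))

    def ratio(num, den, what):
        if den <= 0.0:
            raise DegenerateResponseError(
                f"{what} is undefined: conditioning event has probability 0"
            )
        return num / den

    # correct cells: (S2, "S2") and (S1, "S1")
    corr_s2 = cell("S2", "S2", "low") + cell("S2", "S2", "high")
    inc_s2 = cell("S1", "S2", "low") + cell("S1", "S2", "high")
    corr_s1 = cell("S1", "S1", "low") + cell("S1", "S1", "high")
    inc_s1 = cell("S2", "S1", "low") + cell("S2", "S1", "high")

    hr2_s2 = ratio(cell("S2", "S2", "high"), corr_s2, 'HR2,"S2"')
    far2_s2 = ratio(cell("S1", "S2", "high"), inc_s2, 'FAR2,"S2"')
    hr2_s1 = ratio(cell("S1", "S1", "high"), corr_s1, 'HR2,"S1"')
    far2_s1 = ratio(cell("S2", "S1", "high"), inc_s1, 'FAR2,"S1"')

    p_correct1 = corr_s2 + corr_s1
    p_high_correct = cell("S2", "S2", "high") + cell("S1", "S1", "high")
    p_high_incorrect = cell("S1", "S2", "high") + cell("S2", "S1", "high")
    hr2 = ratio(p_high_correct, p_correct1, "HR2")
    far2 = ratio(p_high_incorrect, 1.0 - p_correct1, "FAR2")
    p_correct2 = p_correct1 * hr2 + (1.0 - p_correct1) * (1.0 - far2)

    p_resp_s2 = resp_mass("S2")
    p_resp_s1 = resp_mass("S1")
    p_corr1_g_s2 = ratio(corr_s2, p_resp_s2, 'p(correct1|"S2")')
    p_corr1_g_s1 = ratio(corr_s1, p_resp_s1, 'p(correct1|"S1")')
    p_correct2_s2 = p_corr1_g_s2 * hr2_s2 + (1.0 - p_corr1_g_s2) * (1.0 - far2_s2)
    p_correct2_s1 = p_corr1_g_s1 * hr2_s1 + (1.0 - p_corr1_g_s1) * (1.0 - far2_s1)

    p_high = p_high_correct + p_high_incorrect
    p_high_s2 = ratio(
        cell("S1", "S2", "high") + cell("S2", "S2", "high"), p_resp_s2,
        'p(high|"S2")',
    )
    p_high_s1 = ratio(
        cell("S1", "S1", "high") + cell("S2", "S1", "high"), p_resp_s1,
        'p(high|"S1")',
    )

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
# outcome curves under a process model
# ---------------------------------------------------------------------------

def _reward_matrix_for_context(context: str, extras) -> RewardMatrix2:
    """Reduce a context to an equivalent type 2 payoff matrix.

    Accuracy is reward with the unit matrix (Q2 = 1); calibration with
    threshold odds O_T is reward with Q2 = O_T (the two closed forms are
    identical, and the equivalence is exact for any generative model whose
    objective is evaluated through the same confidence cells).
    """
    if context == "reward":
        if not isinstance(extras, RewardMatrix2):
            raise TypeError("reward context requires a RewardMatrix2")
        return extras
    if context == "accuracy":
        return RewardMatrix2.from_quotient(1.0)
    if context == "calibration":
        if not isinstance(extras, CalibrationTarget):
            raise TypeError("calibration context requires a CalibrationTarget")
        return RewardMatrix2.from_quotient(extras.O_T)
    raise ValueError(f"unknown context {context!r}")


def _exact_curve_masses(pm, params, response, grid):
    """Stimulus-conditional high-confidence masses along a c2 grid."""
    c1 = params.c1
    if response == "S2":
        hc_S2 = _mass_upper(params.mu_S2, c1, grid, pm.k, pm.sigma2)
        hc_S1 = _mass_upper(params.mu_S1, c1, grid, pm.k, pm.sigma2)
    else:
        hc_S2 = _mass_lower(params.mu_S2, c1, grid, pm.k, pm.sigma2)
        hc_S1 = _mass_lower(params.mu_S1, c1, grid, pm.k, pm.sigma2)
    return hc_S1, hc_S2


def model_outcome_curve(
    context: str,
    pm: ProcessModelParams,
    params: SDTParams,
    extras=None,
    response: str = "S2",
    grid=None,
    engine: str = "exact",
    n: int = 10**6,
    seed=None,
) -> OutcomeCurve:
    """Objective as a function of the response's c2 under a process model.

    ``engine="exact"`` evaluates bivariate orthant masses; ``engine="mc"``
    simulates ``n`` trials once and re-scores every grid point on the same
    draws (common random numbers), which keeps the curve smooth and the
    argmax stable. Contexts: "reward", "hf", "accuracy", "calibration"
    (the last two map onto reward with Q2 = 1 and Q2 = O_T respectively).
    """
    if response not in ("S1", "S2"):
        raise ValueError(f'response must be "S1" or "S2", got {response!r}')
    if grid is None:
        grid = default_grid(params.c1, response)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")

    p_S1, p_S2 = params.p_S1, params.p_S2
    t1 = type1_summary(params)
    if response == "S2":
        corr = p_S2 * t1.HR1       # p(stim S2, resp "S2")
        inc = p_S1 * t1.FAR1       # p(stim S1, resp "S2")
        corr_stim = "S2"
    else:
        corr = p_S1 * (1.0 - t1.FAR1)
        inc = p_S2 * (1.0 - t1.HR1)
        corr_stim = "S1"
    p_resp = corr + inc
    if p_resp <= 0.0:
        raise DegenerateResponseError(
            f"response {response!r} has probability 0"
        )

    if engine == "exact":
        hc_S1, hc_S2 = _exact_curve_masses(pm, params, response, grid)
        corr_hc = (p_S2 * hc_S2) if corr_stim == "S2" else (p_S1 * hc_S1)
        inc_hc = (p_S1 * hc_S1) if corr_stim == "S2" else (p_S2 * hc_S2)
    elif engine == "mc":
        corr_hc, inc_hc, corr, inc = _mc_curve_masses(
            pm, params, response, grid, n, seed
        )
        p_resp = corr + inc
        if p_resp <= 0.0:
            raise DegenerateResponseError(
                f"response {response!r} was never produced in the simulation"
            )
    else:
        raise ValueError(f'engine must be "exact" or "mc", got {engine!r}')

    ranking = None
    if context == "hf":
        if corr <= 0.0 or inc <= 0.0:
            raise DegenerateResponseError(
                "HR2/FAR2 undefined: empty correct or incorrect cell"
            )
        values = corr_hc / corr - inc_hc / inc
    else:
        rm = _reward_matrix_for_context(context, extras)
        # constant + variable split: the variable part orders grid points
        # at full relative precision even when the objective is nearly flat
        # (see OutcomeCurve.ranking_values)
        const = (corr * rm.R_miss2 + inc * rm.R_CR2) / p_resp
        ranking = (
            corr_hc * (rm.R_hit2 - rm.R_miss2)
            - inc_hc * (rm.R_CR2 - rm.R_FA2)
        ) / p_resp
        # for context "accuracy" the unit payoffs make this exactly
        # p(correct2 | response)
        values = const + ranking
    return OutcomeCurve(
        context=context,
        response=response,
        c1=params.c1,
        grid=grid,
        values=np.asarray(values, dtype=float),
        ranking_values=None if ranking is None else np.asarray(ranking),
    )


def _mc_curve_masses(pm, params, response, grid, n, seed):
    """Empirical joint masses p(stim-class, resp, high conf) along a grid."""
    if seed is None:
        raise ValueError("the Monte-Carlo engine requires a seed")
    rng = np.random.default_rng(seed)
    is_s2 = rng.random(n) < params.p_S2
    mu = np.where(is_s2, params.mu_S2, params.mu_S1)
    x1 = mu + rng.standard_normal(n)
    x2 = (1.0 - pm.k) * x1 + pm.sigma2 * rng.standard_normal(n)

    resp_s2 = x1 > params.c1
    if response == "S2":
        mask = resp_s2
        corr_mask = mask & is_s2
        inc_mask = mask & ~is_s2
    else:
        mask = ~resp_s2
        corr_mask = mask & ~is_s2
        inc_mask = mask & is_s2

    x2_corr = np.sort(x2[corr_mask])
    x2_inc = np.sort(x2[inc_mask])
    if response == "S2":  # high iff x2 > c2
        corr_hc = x2_corr.size - np.searchsorted(x2_corr, grid, side="right")
        inc_hc = x2_inc.size - np.searchsorted(x2_inc, grid, side="right")
    else:  # high iff x2 < c2
        corr_hc = np.searchsorted(x2_corr, grid, side="left")
        inc_hc = np.searchsorted(x2_inc, grid, side="left")
    return (
        corr_hc / n,
        inc_hc / n,
        x2_corr.size / n,
        x2_inc.size / n,
    )


# ---------------------------------------------------------------------------
# model-aware optimization
# ---------------------------------------------------------------------------

def _naive_optimum(context, params, extras) -> OptimalCriteria:
    """Closed-form optimum ignoring the process model (sigma2 = 0, k = 0)."""
    if context == "accuracy":
        return c2_opt_accuracy(params)
    if context == "reward":
        return c2_opt_reward(params, extras)
    if context == "calibration":
        return c2_opt_calibration(params, extras)
    if context == "hf":
        return c2_opt_hf(params)
    raise ValueError(f"unknown context {context!r}")


def optimize_c2_under_model(
    context: str,
    pm: ProcessModelParams,
    params: SDTParams,
    extras=None,
    grid=None,
    engine: str = "exact",
    n: int = 10**6,
    seed=None,
) -> tuple[OptimalCriteria, dict[str, OutcomeCurve]]:
    """Model-aware optimal type 2 criteria by grid search, per response.

    Returns the optimum (with clipping flags marking argmax at c1) and the
    full outcome curve for each response. ``grid``, if given, applies to
    the "S2" side and is mirrored for "S1"; by default the oracle's
    standard grid is used. With the MC engine both response curves are
    scored on the same simulated trials.
    """
    if grid is not None:
        grid_s2 = np.asarray(grid, dtype=float)
        grid_s1 = (2.0 * params.c1 - grid_s2)[::-1]
    else:
        grid_s2 = default_grid(params.c1, "S2")
        grid_s1 = default_grid(params.c1, "S1")

    curves = {}
    stars = {}
    for response, g in (("S1", grid_s1), ("S2", grid_s2)):
        curve = model_outcome_curve(
            context, pm, params, extras,
            response=response, grid=g, engine=engine, n=n, seed=seed,
        )
        curves[response] = curve
        stars[response], _ = argmax_c2(curve)
    step = grid_s2[1] - grid_s2[0] if grid_s2.size > 1 else 0.0
    opt = OptimalCriteria(
        context=context,
        c1_star=None,
        c2_S1_star=stars["S1"],
        c2_S2_star=stars["S2"],
        clipped_S1=abs(stars["S1"] - params.c1) <= step / 2,
        clipped_S2=abs(stars["S2"] - params.c1) <= step / 2,
    )
    return opt, curves


def cost_of_ignoring_suboptimality(
    context: str,
    pm: ProcessModelParams,
    params: SDTParams,
    extras=None,
    grid=None,
    engine: str = "exact",
    n: int = 10**6,
    seed=None,
) -> dict[str, float]:
    """Outcome lost by using the standard-SDT criteria under a process model.

    For each response: the model-aware optimal outcome minus the outcome at
    the closed-form (sigma2 = 0, k = 0) criterion, both evaluated under the
    process model. The naive criterion is included in the candidate set, so
    each cost is >= 0 by construction; it is 0 when the model is standard.
    "overall" combines responses: response-probability-weighted for
    reward-like objectives, summed for hf (the overall objective is
    additive in the per-response terms).
    """
    naive = _naive_optimum(context, params, extras)
    opt, curves = optimize_c2_under_model(
        context, pm, params, extras, grid=grid, engine=engine, n=n, seed=seed
    )
    t1 = type1_summary(params)
    weights = {"S1": t1.p_resp_S1, "S2": t1.p_resp_S2}
    naive_c2 = {"S1": naive.c2_S1_star, "S2": naive.c2_S2_star}
    costs: dict[str, float] = {}
    overall = 0.0
    for response in ("S1", "S2"):
        point = model_outcome_curve(
            context, pm, params, extras,
            response=response,
            grid=np.array([naive_c2[response]]),
            engine=engine, n=n, seed=seed,
        )
        naive_val = float(point.values[0])
        _, aware_val = argmax_c2(curves[response])
        aware_val = max(aware_val, naive_val)
        cost = aware_val - naive_val
        costs[response] = cost
        overall += cost * (weights[response] if context != "hf" else 1.0)
    costs["overall"] = overall
    return costs


def sweep_parameter(
    values,
    which: str,
    params: SDTParams,
    contexts=("reward", "hf"),
    q2: float = 3.0,
    crit_offset: float = 1.0,
    n_fit: float = 1e5,
    loss_sigma2: float = DEFAULT_LOSS_SIGMA2,
    grid=None,
    engine: str = "exact",
    n: int = 10**6,
    seed=None,
) -> pd.DataFrame:
    """Metacognitive efficiency and model-aware optima along a parameter grid.

    For each value of ``which`` ("sigma2" or "k"), builds the process
    model, computes M_ratio (meta-d'/d') from expected confidence counts at
    the criterion policy c2 = c1 +/- crit_offset, and finds the model-aware
    optimal c2 per context. Returns a tidy DataFrame with one row per
    parameter value.
    """
    from .metad import expected_counts, fit_metad  # deferred: metad imports us

    if which not in ("sigma2", "k"):
        raise ValueError(f'which must be "sigma2" or "k", got {which!r}')
    crit = Type2Criteria(params.c1 - crit_offset, params.c1 + crit_offset)
    rm = RewardMatrix2.from_quotient(q2)
    rows = []
    for v in np.asarray(values, dtype=float):
        if which == "sigma2":
            pm = ProcessModelParams.noise(v)
        else:
            pm = ProcessModelParams.loss(v, loss_sigma2)
        counts = expected_counts(pm, params, crit, n_fit)
        fit = fit_metad(counts)
        row = {"parameter": which, "value": float(v), "m_ratio": fit.m_ratio,
               "meta_d": fit.meta_d}
        for context in contexts:
            extras = rm if context == "reward" else None
            opt, _ = optimize_c2_under_model(
                context, pm, params, extras,
                grid=grid, engine=engine, n=n, seed=seed,
            )
            row[f"c2_S2_star_{context}"] = opt.c2_S2_star
            row[f"c2_S1_star_{context}"] = opt.c2_S1_star
        rows.append(row)
    return pd.DataFrame(rows)
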