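"""Brute-force outcome curves and grid-search maximization.

This module evaluates each optimization objective on a dense grid of
candidate type 2 criteria, independently of the closed forms in
:mod:`metacrit.optimal_criteria`. Its whole purpose is to serve as a
numerical oracle: for every context, the argmax of the corresponding curve
must reproduce the closed-form optimum to within one grid step.

The default grid covers the response's side of the decision axis out to 6
units from c1 at a step of 1e-3; every optimum with Q2 or O_T up to 100 and
d' >= 0.25 lies well inside this range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .sdt_core import (
    CalibrationTarget,
    RewardMatrix2,
    SDTParams,
    type1_summary,
    p_correct_given_x,
)

__all__ = [
    "OutcomeCurve",
    "default_grid",
    "outcome_curve",
    "argmax_c2",
    "calibration_crossing",
]

DEFAULT_SPAN = 6.0
DEFAULT_STEP = 1e-3


@dataclass(frozen=True)
class OutcomeCurve:
    """An objective evaluated along a grid of candidate type 2 criteria.

    ``ranking_values``, when present, is the curve minus its
    criterion-independent constant. It orders the grid points identically
    to ``values`` but retains full relative precision far in the tails,
    where the criterion-dependent variation of the objective can fall below
    the double-precision resolution of the constant; :func:`argmax_c2` uses
    it to locate the maximum.
    """

    context: str
    response: str
    c1: float
    grid: np.ndarray
    values: np.ndarray
    ranking_values: np.ndarray | None = None

    def __post_init__(self):
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValueError("grid and values must be matching 1-D arrays")
        if (
            self.ranking_values is not None
            and self.ranking_values.shape != self.grid.shape
        ):
            raise ValueError("ranking_values must match the grid shape")


def default_grid(
    c1: float,
    response: str,
    span: float = DEFAULT_SPAN,
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Candidate criteria on the response's side of c1.

    For "S2" responses the interval [c1, c1 + span]; for "S1" responses the
    mirrored [c1 - span, c1], both inclusive of c1.
    """
    n = int(round(span / step))
    offsets = np.arange(n + 1) * step
    if response == "S2":
        return c1 + offsets
    if response == "S1":
        return (c1 - offsets)[::-1]
    raise ValueError(f'response must be "S1" or "S2", got {response!r}')


def _validate_grid(grid: np.ndarray, c1: float, response: str) -> None:
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    tol = 1e-12
    if response == "S2" and grid[0] < c1 - tol:
        raise ValueError('grid for "S2" responses must lie at or above c1')
    if response == "S1" and grid[-1] > c1 + tol:
        raise ValueError('grid for "S1" responses must lie at or below c1')


def _curve_masses(params: SDTParams, response: str, grid: np.ndarray):
    """Joint masses: (correct cell, incorrect cell, high-conf parts thereof).

    "Correct" and "incorrect" are relative to the response: for "S2"
    responses the correct cell is (stimulus S2, x > c1) and the incorrect
    cell (stimulus S1, x > c1); mirrored for "S1". The high-confidence
    masses are evaluated along the grid.
    """
    d, c1 = params.d_prime, params.c1
    p_S1, p_S2 = params.p_S1, params.p_S2
    if response == "S2":
        corr = p_S2 * ndtr(-(c1 - d / 2.0))
        inc = p_S1 * ndtr(-(c1 + d / 2.0))
        corr_hc = p_S2 * ndtr(-(grid - d / 2.0))
        inc_hc = p_S1 * ndtr(-(grid + d / 2.0))
    else:
        corr = p_S1 * ndtr(c1 + d / 2.0)
        inc = p_S2 * ndtr(c1 - d / 2.0)
        corr_hc = p_S1 * ndtr(grid + d / 2.0)
        inc_hc = p_S2 * ndtr(grid - d / 2.0)
    return corr, inc, corr_hc, inc_hc


def _accuracy_curve(params: SDTParams, response: str, grid: np.ndarray):
    """Response-specific type 2 accuracy as a function of the response's c2.

    p(correct2 | response) = [corr_hc + (inc - inc_hc)] / p(response).
    Returns (values, ranking): the curve and its variable part.
    """
    corr, inc, corr_hc, inc_hc = _curve_masses(params, response, grid)
    g = (corr_hc - inc_hc) / (corr + inc)
    return inc / (corr + inc) + g, g


def _reward_curve(
    params: SDTParams, rm: RewardMatrix2, response: str, grid: np.ndarray
):
    """Conditional expected type 2 reward as a function of the response's c2.

    Returns (values, ranking): the curve and its variable part.
    """
    corr, inc, corr_hc, inc_hc = _curve_masses(params, response, grid)
    const = (corr * rm.R_miss2 + inc * rm.R_CR2) / (corr + inc)
    g = (
        corr_hc * (rm.R_hit2 - rm.R_miss2)
        - inc_hc * (rm.R_CR2 - rm.R_FA2)
    ) / (corr + inc)
    return const + g, g


def _hf_curve(params: SDTParams, response: str, grid: np.ndarray):
    """Response-specific HR2 - FAR2 as a function of the response's c2."""
    d, c1 = params.d_prime, params.c1
    if response == "S2":
        hr2 = ndtr(-(grid - d / 2.0)) / ndtr(-(c1 - d / 2.0))
        far2 = ndtr(-(grid + d / 2.0)) / ndtr(-(c1 + d / 2.0))
    else:
        hr2 = ndtr(grid + d / 2.0) / ndtr(c1 + d / 2.0)
        far2 = ndtr(grid - d / 2.0) / ndtr(c1 - d / 2.0)
    return hr2 - far2


def outcome_curve(
    context: str,
    params: SDTParams,
    extras=None,
    response: str = "S2",
    grid=None,
) -> OutcomeCurve:
    """Evaluate one optimization objective along a grid of c2 candidates.

    ``extras`` is a :class:`RewardMatrix2` for the reward context, a
    :class:`CalibrationTarget` for calibration (where the "curve" is
    p(correct1 | x) itself and the optimum is a crossing, not a maximum),
    and ignored otherwise. Curves are response-specific; each objective
    depends only on the criterion of its own response.
    """
    if response not in ("S1", "S2"):
        raise ValueError(
            f'response must be "S1" or "S2", got {response!r} '
            "(overall objectives decompose per response)"
        )
    if grid is None:
        grid = default_grid(params.c1, response)
    grid = np.asarray(grid, dtype=float)
    _validate_grid(grid, params.c1, response)

    ranking = None
    if context == "accuracy":
        values, ranking = _accuracy_curve(params, response, grid)
    elif context == "reward":
        if not isinstance(extras, RewardMatrix2):
            raise TypeError("reward context requires a RewardMatrix2")
        values, ranking = _reward_curve(params, extras, response, grid)
    elif context == "calibration":
        values = np.asarray(p_correct_given_x(params, grid), dtype=float)
    elif context == "hf":
        values = _hf_curve(params, response, grid)
    else:
        raise ValueError(f"unknown context {context!r}")
    return OutcomeCurve(
        context=context,
        response=response,
        c1=params.c1,
        grid=grid,
        values=np.asarray(values, dtype=float),
        ranking_values=None if ranking is None else np.asarray(ranking),
    )


def argmax_c2(curve: OutcomeCurve) -> tuple[float, float]:
    """Grid point with maximal outcome, ties broken toward c1 (liberal).

    Returns (criterion, value). The maximum is located on the curve's
    well-conditioned ranking channel when available (see
    :class:`OutcomeCurve`); the reported value comes from ``values``.
    Raises on an all-NaN curve.
    """
    ranking = (
        curve.ranking_values if curve.ranking_values is not None else curve.values
    )
    finite = np.isfinite(ranking)
    if not finite.any():
        raise ValueError("cannot take argmax of an all-NaN outcome curve")
    vmax = np.nanmax(ranking)
    at_max = np.flatnonzero(ranking == vmax)
    best = at_max[np.argmin(np.abs(curve.grid[at_max] - curve.c1))]
    return float(curve.grid[best]), float(curve.values[best])


def calibration_crossing(
    params: SDTParams,
    target: CalibrationTarget,
    response: str = "S2",
    span: float = DEFAULT_SPAN,
    xtol: float = 1e-12,
) -> float:
    """Criterion at which p(correct1 | x) crosses the threshold accuracy.

    Root of p(correct1 | x) - p_correct_T on the response's side of c1,
    found by bracketed root-finding (Brent); clipped at c1 when the whole
    response region already exceeds the threshold. Independent check of the
    closed-form calibration optimum.
    """
    if response not in ("S1", "S2"):
        raise ValueError(f'response must be "S1" or "S2", got {response!r}')
    c1 = params.c1
    sign = 1.0 if response == "S2" else -1.0

    def f(x):
        return float(p_correct_given_x(params, x)) - target.p_correct_T

    lo = c1 + sign * 1e-9
    hi = c1 + sign * span
    f_lo, f_hi = f(lo), f(hi)
    if f_lo >= 0.0:
        # already above threshold throughout: consistency bound is active
        return c1
    if f_hi <= 0.0:
        raise ValueError(
            "threshold accuracy not reached within the search span; "
            "increase span"
        )
    a, b = (lo, hi) if response == "S2" else (hi, lo)
    return float(brentq(f, a, b, xtol=xtol))
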