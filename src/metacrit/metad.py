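"""Meta-d' and M_ratio estimation from binary-confidence count data.

meta-d' answers the question: what sensitivity would a hypothetical
SDT-ideal observer need in order to reproduce the observed type 2 (confidence)
data? It is estimated by maximum likelihood on the confidence counts
conditional on each type 1 response, under the equal-variance model, with
the type 1 criterion preserved on the relative scale: the fit uses
meta_c = c1 * meta_d / d', so the hypothetical observer keeps the same
criterion-to-sensitivity ratio c' = c1/d' as the actual one. M_ratio =
meta-d'/d' equals 1 when the standard SDT model holds and falls below 1
under type 2 noise or signal loss.

Only binary (low/high) confidence is supported: one type 2 criterion per
response, three free parameters (meta_d, c2_S1, c2_S2) in total. Zero cells
are handled by adding 0.5 to every cell iff any cell is zero (a standard
log-linear correction; switchable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .errors import FitError
from .process_models import ProcessModelParams, cell_probabilities
from .sdt_core import SDTParams, Type2Criteria

__all__ = [
    "ConfidenceCounts",
    "MetaDFit",
    "counts_from_trials",
    "expected_counts",
    "fit_metad",
    "sweep_mratio",
]

STIMULI = ("S1", "S2")
RESPONSES = ("S1", "S2")
CONFIDENCES = ("low", "high")


@dataclass(frozen=True)
class ConfidenceCounts:
    """2 x 2 x 2 table of trial counts.

    ``counts[i, j, k]`` indexes (stimulus, response, confidence) in the
    order (S1, S2) x ("S1", "S2") x (low, high). Counts may be fractional
    (expected counts); they must be non-negative with positive total.
    """

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (2, 2, 2):
            raise ValueError(
                f"counts must have shape (2, 2, 2), got {arr.shape}"
            )
        if np.any(arr < 0) or not np.isfinite(arr).all():
            raise ValueError("counts must be finite and non-negative")
        if arr.sum() <= 0:
            raise ValueError("total count must be positive")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def type1_marginals(self) -> np.ndarray:
        """Counts by (stimulus, response), summing over confidence."""
        return self.counts.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Tidy 8-row frame with columns stimulus, response, confidence, count."""
        rows = [
            {
                "stimulus": s,
                "response": r,
                "confidence": c,
                "count": self.counts[i, j, k],
            }
            for i, s in enumerate(STIMULI)
            for j, r in enumerate(RESPONSES)
            for k, c in enumerate(CONFIDENCES)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfidenceCounts":
        arr = np.zeros((2, 2, 2))
        for _, row in df.iterrows():
            try:
                i = STIMULI.index(row["stimulus"])
                j = RESPONSES.index(row["response"])
                k = CONFIDENCES.index(row["confidence"])
            except ValueError as exc:
                raise ValueError(f"unknown category label in row: {dict(row)}") from exc
            arr[i, j, k] += float(row["count"])
        return cls(arr)


def counts_from_trials(trials: pd.DataFrame) -> ConfidenceCounts:
    """Cross-tabulate a trial table into confidence counts.

    The table must have columns stimulus, response, confidence with labels
    in {S1, S2} x {S1, S2} x {low, high}; any other label raises.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    arr = np.zeros((2, 2, 2))
    for col, allowed in (
        ("stimulus", STIMULI),
        ("response", RESPONSES),
        ("confidence", CONFIDENCES),
    ):
        bad = set(trials[col].unique()) - set(allowed)
        if bad:
            raise ValueError(f"unknown {col} labels: {sorted(bad)}")
    grouped = trials.groupby(["stimulus", "response", "confidence"]).size()
    for (s, r, c), n in grouped.items():
        arr[STIMULI.index(s), RESPONSES.index(r), CONFIDENCES.index(c)] = n
    return ConfidenceCounts(arr)


def expected_counts(
    pm: ProcessModelParams,
    params: SDTParams,
    crit: Type2Criteria,
    n: float,
) -> ConfidenceCounts:
    """Expected (fractional) confidence counts under a process model.

    Deterministic alternative to simulating and tabulating n trials; the
    multinomial likelihood accepts fractional counts, so fits on expected
    counts give noise-free parameter sweeps.
    """
    cells = cell_probabilities(pm, params, crit)
    arr = np.zeros((2, 2, 2))
    for (s, r, c), p in cells.items():
        arr[STIMULI.index(s), RESPONSES.index(r), CONFIDENCES.index(c)] = n * p
    return ConfidenceCounts(arr)


@dataclass(frozen=True)
class MetaDFit:
    """Result of a meta-d' fit.

    ``d_prime`` and ``c1`` come from the type 1 marginals
    (inverse-normal of HR1 and FAR1); ``meta_d`` and the type 2 criteria
    maximize the confidence likelihood conditional on response;
    ``meta_c = c1 * meta_d / d_prime`` by convention; ``m_ratio`` =
    meta_d / d_prime; ``logL`` is the maximized conditional log-likelihood.
    """

    meta_d: float
    meta_c: float
    meta_c2_S1: float
    meta_c2_S2: float
    m_ratio: float
    logL: float
    d_prime: float
    c1: float


_EPS = 1e-12


def _p_high(meta_d, c_ratio, t1, t2):
    """p(high | stimulus, response) for all four cells under the meta model.

    Returns a (2, 2) array indexed (stimulus, response).
    """
    meta_c = c_ratio * meta_d
    c2_s1 = meta_c - t1
    c2_s2 = meta_c + t2
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    p = np.empty((2, 2))
    # "S1" responses: high iff x < c2_S1, conditional on x < meta_c
    denom_s1 = ndtr(meta_c - mus)
    p[:, 0] = ndtr(c2_s1 - mus) / np.maximum(denom_s1, _EPS)
    # "S2" responses: high iff x > c2_S2, conditional on x > meta_c
    denom_s2 = ndtr(-(meta_c - mus))
    p[:, 1] = ndtr(-(c2_s2 - mus)) / np.maximum(denom_s2, _EPS)
    return np.clip(p, _EPS, 1.0 - _EPS)


def fit_metad(
    counts: ConfidenceCounts, zero_cell_correction: bool = True
) -> MetaDFit:
    """Maximum-likelihood meta-d' from binary-confidence counts.

    The three free parameters (meta_d and the two type 2 criteria) are
    optimized with bounded L-BFGS-B from multiple starts
    (meta_d in {0.5, 1.0, 1.5} x d') to avoid local optima; meta_d is
    bounded in [0, 5 d'].

    Raises :class:`FitError` when a response cell is empty, when the type 1
    marginals imply d' <= 0, or when the confidence column is constant
    (type 2 data uninformative).
    """
    arr = counts.counts
    if zero_cell_correction and np.any(arr == 0):
        arr = arr + 0.5

    raw = counts.counts
    if np.any(raw.sum(axis=(0, 2)) <= 0):
        raise FitError("a response cell is empty; meta-d' is not identified")
    raw_conf = raw.sum(axis=(0, 1))
    if raw_conf[0] == 0 or raw_conf[1] == 0:
        raise FitError(
            "confidence column is constant; type 2 data are uninformative"
        )
    marg = arr.sum(axis=2)  # (stimulus, response)

    hr1 = marg[1, 1] / marg[1].sum()
    far1 = marg[0, 1] / marg[0].sum()
    if not (0.0 < far1 < 1.0 and 0.0 < hr1 < 1.0):
        raise FitError(
            "type 1 marginals are at floor/ceiling; apply the zero-cell "
            "correction or collect more data"
        )
    d_prime = float(ndtri(hr1) - ndtri(far1))
    c1 = float(-0.5 * (ndtri(hr1) + ndtri(far1)))
    if d_prime <= 0:
        raise FitError(
            f"type 1 marginals imply d' = {d_prime:.4f} <= 0; the binary "
            "meta-d' fit requires d' > 0"
        )
    c_ratio = c1 / d_prime

    n_high = arr[:, :, 1]
    n_low = arr[:, :, 0]

    def nll(theta):
        meta_d, t1, t2 = theta
        p = _p_high(meta_d, c_ratio, t1, t2)
        return -float(
            np.sum(n_high * np.log(p) + n_low * np.log1p(-p))
        )

    bounds = [(1e-6, 5.0 * d_prime), (0.0, 12.0), (0.0, 12.0)]
    # data-driven criterion starts: place c2 so that, under meta_c ~ 0, the
    # model-implied p(high | response) matches the observed rate; essential
    # when high confidence is rare and the likelihood is nearly flat far
    # from the optimum
    p_obs = n_high.sum(axis=0) / np.maximum(arr.sum(axis=(0, 2)), _EPS)
    t_data = np.maximum(
        0.1, -ndtri(np.clip(0.5 * p_obs, _EPS, 0.5 - _EPS))
    )
    t_starts = [(0.25, 0.25), (1.0, 1.0), (float(t_data[0]), float(t_data[1]))]
    best = None
    for scale in (0.5, 1.0, 1.5):
        for t1_0, t2_0 in t_starts:
            x0 = np.array([scale * d_prime, t1_0, t2_0])
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("meta-d' optimization failed to converge")

    meta_d, t1, t2 = best.x
    meta_c = c_ratio * meta_d
    return MetaDFit(
        meta_d=float(meta_d),
        meta_c=float(meta_c),
        meta_c2_S1=float(meta_c - t1),
        meta_c2_S2=float(meta_c + t2),
        m_ratio=float(meta_d / d_prime),
        logL=-float(best.fun),
        d_prime=d_prime,
        c1=c1,
    )


def sweep_mratio(
    values,
    which: str,
    params: SDTParams,
    crit_offset: float = 1.0,
    n: float = 1e5,
    engine: str = "exact",
    seed=None,
    loss_sigma2: float = 0.1,
) -> pd.DataFrame:
    """M_ratio along a grid of type 2 noise (sigma2) or signal-loss (k) values.

    ``engine="exact"`` fits noise-free expected counts; ``engine="mc"``
    simulates ``n`` trials per value (seed required) and tabulates. The
    confidence criteria follow the policy c2 = c1 +/- crit_offset.
    """
    from .process_models import simulate_trials  # local: keep import graph flat

    if which not in ("sigma2", "k"):
        raise ValueError(f'which must be "sigma2" or "k", got {which!r}')
    crit = Type2Criteria(params.c1 - crit_offset, params.c1 + crit_offset)
    rows = []
    for i, v in enumerate(np.asarray(values, dtype=float)):
        if which == "sigma2":
            pm = ProcessModelParams.noise(v)
        else:
            pm = ProcessModelParams.loss(v, loss_sigma2)
        if engine == "exact":
            counts = expected_counts(pm, params, crit, n)
        elif engine == "mc":
            if seed is None:
                raise ValueError("the Monte-Carlo engine requires a seed")
            trials = simulate_trials(pm, params, crit, int(n), int(seed) + i)
            counts = counts_from_trials(trials)
        else:
            raise ValueError(f'engine must be "exact" or "mc", got {engine!r}')
        fit = fit_metad(counts)
        rows.append(
            {
                "parameter": which,
                "value": float(v),
                "meta_d": fit.meta_d,
                "d_prime": fit.d_prime,
                "m_ratio": fit.m_ratio,
            }
        )
    return pd.DataFrame(rows)
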