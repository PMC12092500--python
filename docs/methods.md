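# Methods

## Model and coordinate conventions

The package works in the equal-variance SDT coordinate system with the two
stimulus distributions placed symmetrically at ∓d′/2 with unit variance.
This placement (rather than 0 and d′) is load-bearing: it makes the
likelihood ratio of S2 to S1 at any point x equal to e^{x·d′}, so a
criterion c corresponds to the likelihood-ratio criterion β = e^{c·d′} and
the posterior log-odds for S2 are simply x·d′ + ln(p(S2)/p(S1)). All
closed-form optima in `optimal_criteria` are statements about where this
posterior (or a payoff-weighted version of it) crosses a threshold.

The observer responds "S2" for x > c₁, with the tie x = c₁ assigned to
"S1". The tie has probability zero under the continuous model; it is fixed
anyway so that discretized or replayed inputs are bit-reproducible.
Criteria may be ±∞ ("always"/"never" policies); rate formulas take the
limits, and conditioning on a zero-probability response raises a typed
error rather than returning NaN.

Probabilities are computed in double precision with upper-tail masses
evaluated through the complementary normal CDF, so rates stay accurate at
|z| well beyond 6. One further numerical device matters: an outcome curve
far in the tails is a large criterion-independent constant plus a tiny
criterion-dependent part, and the location of its maximum can be flatter
than double-precision resolution of the sum. `OutcomeCurve` therefore
carries a `ranking_values` channel — the curve minus its constant, which
has full relative precision — and `argmax_c2` locates the maximum on that
channel while reporting the outcome value from the full curve. Grid-search
argmaxes then agree with the closed forms to one grid step even where the
objective is numerically flat.

## Optimization contexts

Four objectives are supported; all reduce to placing each response-specific
type 2 criterion at a posterior-odds threshold, clipped at the actual c₁
(consistency constraint), with flags recording when the bound was active:

- **accuracy** — report high confidence iff the type 1 response is more
  likely than not to be correct; both optima sit as close to c₁ᴬ\* as the
  constraints allow. With an accuracy-optimal c₁ the observer never
  reports low confidence, which is why this objective is best read as an
  error-detection policy.
- **reward** — the payoff matrix enters only through the quotient
  Q₂ = (R_CR2 − R_FA2)/(R_hit2 − R_miss2). Q₂ is undefined when either
  difference is zero or the signs differ, and the both-negative case turns
  the stationary point into a minimum; these raise
  `UndefinedQuotientError` / `InvertedRewardError` rather than silently
  "optimizing".
- **calibration** — not a maximization but a policy: high confidence iff
  p(correct₁|x) exceeds a threshold p_T. The optimum is the crossing point
  of the posterior-accuracy curve, verified independently by bracketed
  root-finding (`calibration_crossing`, agreement to 1e−6). Calibration
  with odds O_T and reward with Q₂ = O_T are the same optimum; the CLI
  reports each optimum restated in the other currency.
- **hf** — maximize the response-specific difference between type 2 hit
  and false-alarm rates. The optima depend on c₁ only through the implied
  HR₁/FAR₁ and are nearly flat in d′; the test-suite pins this
  qualitative claim down as "range < 0.25 decision-axis units over
  d′ ∈ [0.5, 5] at c₁ = 0", a bound chosen by evaluating the expression
  over that range, not taken from any external source. Model-implied
  HR₁/FAR₁ are used by default; externally measured rates can be supplied
  and are used verbatim.

At d′ = 0, formulas with d′ in the denominator raise
`ZeroSensitivityError`; genuinely flat objectives (equal-prior accuracy,
HR₁ − FAR₁) return the conventional 0.

Outcome curves are response-specific. Every objective above conditions on
(or decomposes additively across) the two responses, so a curve for
"overall" would add machinery without adding information; requesting one
raises. The default grid covers the response's side of c₁ out to 6 units
at step 1e−3; randomized tests widen the span adaptively when an optimum
lies further out (possible with extreme priors at low d′). Grid ties are
broken toward c₁ (liberal-ward) — an arbitrary but fixed choice.

## Process models of suboptimal metacognition

Type 2 noise (x₂ = x₁ + ε, ε ~ N(0, σ₂²)) and type 2 signal loss
(x₂ = (1−k)x₁ + ε) make confidence operate on degraded evidence. Per
stimulus, (x₁, x₂) are jointly normal with correlation
(1−k)/√((1−k)² + σ₂²); every (stimulus, response, confidence) cell is a
bivariate-normal orthant mass. These masses are computed by Gauss–Legendre
quadrature (240 nodes over ±9.5 SD) of the conditional-normal tail, which
vectorizes over criterion grids; the test-suite cross-checks them against
`scipy.stats.multivariate_normal` and against Monte-Carlo simulation
(agreement within 3–4 standard errors at n = 10⁶). At σ₂ = 0 the event
{x₂ > c₂} collapses to a condition on x₁ and a closed form is used; at
σ₂ = 0, k = 0 every quantity reduces exactly to the standard model. The
fully degenerate combination k = 1, σ₂ = 0 (x₂ ≡ 0) is rejected. The loss
model defaults to σ₂ = 0.1 so that k is the single swept parameter.

**Confidence rule under process models.** The response-specific c₂ is
compared against x₂ even when x₂ falls on the far side of c₁ from the
response: a trial with response "S2" and x₂ < c₂,"S2" is simply low
confidence. No re-evaluation of the type 1 response occurs. This is the
single place where a modelling convention had to be fixed rather than
derived; it is stated here prominently because alternative conventions
(e.g. treating such trials as "detected errors") would change the curves.

Closed forms are unavailable under these models, so optima come from grid
search over the outcome curves, evaluated either exactly (orthant masses)
or by Monte-Carlo. The MC engine draws stimuli, x₁ and ε once per curve
and re-scores every grid point on the same draws (common random numbers),
which removes between-point sampling jitter from the argmax; a seed is
mandatory. The default MC size is 10⁶ trials per curve; tests and the
parameter sweeps use 10⁵–10⁶ and exact engines where possible, sizes
chosen as good bias/variance compromises at desk scale.

**Calibration under a process model** is defined through the exact
Q₂ = O_T equivalence: the calibration optimum is computed as the reward
optimum with Q₂ = O_T. Under the standard model this is an identity; under
a process model it amounts to *defining* calibrated confidence as the
policy maximizing the corresponding expected reward, which keeps the four
contexts on one footing (the alternative — thresholding
p(correct₁|x₂) — presumes the observer knows the degradation mechanism
trial-by-trial, a stronger assumption than the package wants to build in).

`cost_of_ignoring_suboptimality` reports, per response, the model-aware
optimal outcome minus the outcome at the standard-SDT criteria, both
evaluated under the process model. The naive criteria are included in the
candidate set, so the cost is ≥ 0 by construction and exactly 0 when the
model is standard. The "overall" entry weights responses by their
probabilities for reward-like objectives and sums them for the HF
objective (whose overall form is additive in the per-response terms).

## Meta-d′ and M_ratio

meta-d′ asks what sensitivity a hypothetical SDT-ideal observer would need
to reproduce the observed confidence data, and M_ratio = meta-d′/d′
indexes metacognitive efficiency (1 under the standard model). The fit is
restricted to binary confidence — one type 2 criterion per response, three
free parameters — because the whole package binarizes confidence.

Conventions, each a deliberate choice:

- d′ and c₁ come from the type 1 marginals by inverse-normal transform.
- The hypothetical observer keeps the actual observer's relative
  criterion: meta_c = c₁ · meta-d′/d′ (the prevailing convention for this
  measure).
- Likelihood: product over (stimulus, response) cells of Bernoulli
  likelihoods of the high/low counts, with cell probabilities given by
  truncated-normal tail ratios under (meta-d′, meta_c, c₂ pair).
- Zero cells: +0.5 added to every cell iff any cell is zero (switchable).
- Optimization: L-BFGS-B with meta-d′ ∈ [0, 5d′], criterion offsets in
  [0, 12], multi-start over meta-d′ ∈ {0.5, 1, 1.5}·d′ crossed with three
  criterion starts including a data-driven one that matches the observed
  p(high | response) under meta_c ≈ 0. The data-driven start matters: when
  high confidence is rare (strong signal loss with fixed criteria) the
  likelihood is nearly flat far from the optimum and naive starts stall.

Parameter recovery on noise-free expected counts returns meta-d′ = d′ to
2e−3 across d′ ∈ {1, 2, 3} × c₁ ∈ {−0.5, 0, 0.5}; on simulated data at
n = 10⁵, M_ratio = 1 within 0.05. Sweeps fit expected (fractional) counts
by default, making M_ratio-vs-parameter curves noise-free; the criterion
policy during sweeps is c₂ = c₁ ± 1, configurable.

## Synthetic data

`simulate_trials` is the package's only data source and emulates exactly
the generative model above: i.i.d. trials, Bernoulli stimulus, Gaussian
evidence, deterministic response and confidence rules, reproducible from a
single seed with parameters embedded in the table's metadata. It does not
emulate features of real confidence data such as sequential dependencies,
criterion drift, lapses, response-time coupling, or graded confidence
scales. Passing tests therefore demonstrate internal correctness of the
model, the optima and the estimator — not that any real observer conforms
to the model; applying the optima to real data inherits all the usual SDT
assumptions (equal variance foremost, which is why detection tasks with
unequal-variance structure are out of scope).

## Known limitations

- Equal-variance model only; no zROC fitting.
- Binary confidence only (>2 levels and response-specific meta-d′ are out
  of scope); the calibration framework is the natural extension route.
- Process models are limited to type 2 noise and signal loss, but
  `cell_probabilities`/`model_outcome_curve` only consume the joint
  (x₁, x₂) law through two orthant-mass functions, so adding a new model
  is a single-function extension.
- The posterior-accuracy identity p(correct₁|x = c₂\*) = p_T holds only at
  unclipped calibration optima; at clipped optima the threshold is
  unattainable on that response side.
- A worked-example curiosity: the overall accuracy of the unbiased d′ = 2
  observer is Φ(1) ≈ 0.8413; where 0.843 appears as a calibration
  threshold in examples it is the conventional rounded figure, and the
  package reports the closed-form value.
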