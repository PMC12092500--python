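"""Optimal confidence criteria when metacognition is imperfect.

Adds type 2 noise (x2 = x1 + eps, sigma2 = 0.8) or type 2 signal loss
(x2 = 0.5 x1 + eps, sigma2 = 0.1) to the standard observer (d' = 2,
c1 = 0) and re-optimizes the confidence criteria by exact grid search.
Noise pushes the reward optimum (Q2 = 3) inward (more liberal) but the
HR2 - FAR2 optimum outward (more conservative); signal loss pushes both
inward. The same parameters lower metacognitive efficiency (M_ratio).
"""

import numpy as np

from metacrit import (
    ProcessModelParams,
    RewardMatrix2,
    SDTParams,
    c2_opt_hf,
    c2_opt_reward,
    cost_of_ignoring_suboptimality,
    optimize_c2_under_model,
    sweep_mratio,
)

params = SDTParams(d_prime=2.0, c1=0.0, p_S2=0.5)
rm = RewardMatrix2.from_quotient(3.0)
grid = np.arange(0.0, 3.0 + 1e-9, 2e-3)

print("standard-SDT optima (sigma2 = 0, k = 0):")
print(f"  reward (Q2=3): c2_S2* = {c2_opt_reward(params, rm).c2_S2_star:.3f}")
print(f"  HR2 - FAR2   : c2_S2* = {c2_opt_hf(params).c2_S2_star:.3f}\n")

models = {
    "type 2 noise (sigma2=0.8)": ProcessModelParams.noise(0.8),
    "signal loss (k=0.5, sigma2=0.1)": ProcessModelParams.loss(0.5, 0.1),
}
for name, pm in models.items():
    opt_r, _ = optimize_c2_under_model("reward", pm, params, rm, grid=grid)
    opt_h, _ = optimize_c2_under_model("hf", pm, params, grid=grid)
    cost_h = cost_of_ignoring_suboptimality("hf", pm, params, grid=grid)
    print(f"{name}:")
    print(f"  model-aware reward optimum: c2_S2* = {opt_r.c2_S2_star:.3f}")
    print(f"  model-aware HF optimum    : c2_S2* = {opt_h.c2_S2_star:.3f}")
    print(f"  HF outcome lost if the model is ignored: {cost_h['overall']:.4f}\n")

print("metacognitive efficiency along the noise and loss parameter grids:")
noise = sweep_mratio([0.0, 0.4, 0.8, 1.2], "sigma2", params, n=1e5)
loss = sweep_mratio([0.0, 0.25, 0.5, 0.75], "k", params, n=1e5)
for _, row in noise.iterrows():
    print(f"  sigma2 = {row['value']:.2f} -> M_ratio = {row['m_ratio']:.3f}")
for _, row in loss.iterrows():
    print(f"  k      = {row['value']:.2f} -> M_ratio = {row['m_ratio']:.3f}")
print(
    "\nM_ratio falls monotonically in both parameters, but equal M_ratio\n"
    "under the two mechanisms implies different optimal criteria - the\n"
    "process model matters, not just the efficiency number."
)
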