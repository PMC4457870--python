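"""Robustness: presynaptic flips with threshold re-optimisation, and
heterogeneously correlated inputs.
"""

import numpy as np

from sparseperceptron import (NoiseSpec, PlasticityConfig, error_rates,
                              gen_correlated, gen_lures, gen_patterns,
                              information, optimize_threshold, solve_min_l1,
                              train_online)

# --- presynaptic noise: flip probabilities delta01 = delta10 = delta ----
N, K = 400, 40
patterns = gen_patterns(N, K, seed=20)
w = solve_min_l1(patterns).w
# after rescaling to a unit mean pattern response the useful absolute
# thresholds are O(1), i.e. theta ~ 1/sqrt(N)
theta_grid = np.linspace(0.0, 1.2, 25) / np.sqrt(N)
print("information after per-noise-level threshold re-optimisation "
      "(max-imbalance solution):")
for delta in (0.0, 0.1, 0.3):
    noise = NoiseSpec(delta01=delta, delta10=delta)
    lures = gen_lures(patterns, 20 * K, noise=noise, seed=22)
    theta, C = optimize_threshold(w, patterns, lures, noise, theta_grid,
                                  seed=23)
    print(f"  delta = {delta:.1f}: theta*·sqrt(N) = "
          f"{theta * np.sqrt(N):.2f}, C = {C:.3f} bits/synapse")

# --- heterogeneous input correlations -----------------------------------
print("\nefficiency S under heterogeneous template correlation g:")
for g in (0.0, 0.6):
    p = gen_correlated(500, 50, g, mode="heterogeneous", seed=24)
    lures = gen_lures(p, 500, seed=25)
    for name, wv in (
            ("max imbalance", solve_min_l1(p).w),
            ("balanced", train_online(
                p, PlasticityConfig(epsilon=1 / 500, lam=0.0,
                                    max_epochs=3000, seed=26)).state.w)):
        p10, p01 = error_rates(wv, p, lures)
        C = information(p01, p10, 50, 500)
        F = float(np.mean(wv > 0))
        print(f"  g = {g:.1f}  {name:14s} S = {C / F:.3f}")
print("Distortion degrades recognition smoothly; under heterogeneous "
      "correlations the L1-optimal (imbalanced) rule silences the "
      "low-activity inputs and keeps its efficiency while the balanced "
      "rule deteriorates.")
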