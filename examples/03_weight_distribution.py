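"""Shape of the sparse weight distribution.

Pools the non-zero weights of 30 minimum-L1 solutions (unit-threshold
normalised) and fits the compressed exponential P(w) ∝ exp(−c·w^β).
β = 1 would be exponential (the balanced online rule's shape), β = 2 a
hemi-Gaussian (the QP optimum's shape); the sparse L1 solution sits in
between.
"""

import numpy as np

from sparseperceptron import (fit_compressed_exponential, gen_patterns,
                              normalize_to_unit_threshold, solve_min_l1)

pooled = []
for trial in range(30):
    patterns = gen_patterns(1000, 100, seed=100 + trial)
    sol = solve_min_l1(patterns)
    w = normalize_to_unit_threshold(sol.w, patterns)
    pooled.append(w[w > 0])
pooled = np.concatenate(pooled)

fit = fit_compressed_exponential(pooled)
print(f"pooled {pooled.size} non-zero weights from 30 solutions "
      f"(mean support {pooled.size / 30:.0f} of 1000 synapses)")
print(f"compressed-exponential fit: beta = {fit.beta:.2f}, c = {fit.c:.1f}")
print("beta between 1 and 2 means the surviving weights are stretched "
      "towards larger values than an exponential law: sparsification "
      "concentrates the same total drive on fewer, stronger synapses.")
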