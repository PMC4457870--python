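"""Convergence theory: the margin-based update bound and the empirical
critical imbalance λ_max.
"""

import numpy as np

from sparseperceptron import (ConvergenceParams, PlasticityConfig,
                              balanced_epsilon_max, convergence_bound,
                              gen_patterns, lambda_max_empirical,
                              max_low_fraction, solve_min_l2, train_online)

# certify a margin with a reference solution at threshold theta + kappa
N, K, theta, kappa = 100, 10, 1.0, 0.5
patterns = gen_patterns(N, K, seed=30)
ref = solve_min_l2(patterns, theta=theta + kappa)
q = max_low_fraction(patterns)
eps = 0.9 * balanced_epsilon_max(kappa, N, q)
params = ConvergenceParams(epsilon=eps, theta=theta, lam=0.0, kappa=kappa,
                           l1_star=float(ref.w.sum()),
                           l2_star=float(np.linalg.norm(ref.w)), q=q, N=N)
bound = convergence_bound(params, 0)
res = train_online(patterns, PlasticityConfig(epsilon=eps, theta=theta,
                                              lam=0.0, max_epochs=100_000,
                                              seed=31))
print(f"guaranteed convergence: {bound.guaranteed}, "
      f"bound m* = {bound.m_star} updates")
print(f"simulation converged after {res.updates} updates "
      f"(<= m*: {res.updates <= bound.m_star})")

# empirical critical imbalance at alpha = 0.1
from sparseperceptron import solve_min_l1  # noqa: E402

patterns = gen_patterns(300, 30, seed=32)
cfg = PlasticityConfig(epsilon=1 / 300, lam=0.0, max_epochs=2000)
lam_max, curve = lambda_max_empirical(patterns, cfg,
                                      np.round(np.arange(0, 1.01, 0.1), 2),
                                      lure_factor=10, seed=33)
lp = solve_min_l1(patterns)
print(f"\nempirical lambda_max at alpha = 0.1: {lam_max:.1f}")
print(curve.to_string(index=False,
                      formatters={"S": lambda s: f"{s:.3f}"}))
ratio = curve[curve["converged"]]["epochs"].iloc[-1]
print(f"LP reference: |w*|_1 = {lp.objective:.1f}; the converged state at "
      f"lambda = {lam_max:.1f} needs {ratio} epochs — learning slows as the "
      "imbalance squeezes the solution towards the L1 optimum, and beyond "
      "lambda_max it no longer converges at all.")
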