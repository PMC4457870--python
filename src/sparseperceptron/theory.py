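"""Convergence theory for the imbalanced one-class perceptron.

The convergence proof assumes a feasible reference configuration w* that
solves the task with margin κ ≥ 0, i.e. Σ_i w*_i x_i^k ≥ (θ+κ)√N for all
stored patterns, with w* ≥ 0.  Tracking the cosine
a(m) = w*·w(m)/(‖w*‖₂‖w(m)‖₂) over plasticity events m yields the lower
bound

    a(m) > √(εmN) · S / (‖w*‖₂ · √D),

    S = κ/√N − λ|w*|₁/N − ½ε(1+2λq+λ²q) − qε(1+λ)²,
    D = 2θ/√N + ε(1+2λq+λ²q) + 2qε(1+λ)²,

where q is the maximal fraction of low inputs over the stored patterns.
Since a(m) ≤ 1 (Cauchy–Schwarz), a positive slope factor S guarantees
convergence within m* = ‖w*‖₂²·D/(ε·N·S²) updates.  At λ = 0 the
condition S ≥ 0 reduces to ε ≤ 2κ/[√N(1+2q)]; for λ > 0 a larger margin κ
and a smaller linear norm |w*|₁ are needed to compensate, which is why
the admissible imbalance λ_max shrinks with the memory load α.

``lambda_max_empirical`` estimates λ_max directly by training at
increasing imbalance until the dynamics no longer converges within the
epoch budget (the budget is part of the definition and is recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import count_functional, error_rates, information, efficiency
from .patterns import PatternSet, gen_lures
from .plasticity import PlasticityConfig, train_online

__all__ = [
    "ConvergenceParams",
    "BoundReport",
    "convergence_bound",
    "balanced_epsilon_max",
    "max_low_fraction",
    "lambda_max_empirical",
    "find_lambda_max",
    "exhaustive_testing_gain",
]


@dataclass(frozen=True)
class ConvergenceParams:
    """Inputs to the convergence bound."""

    epsilon: float
    theta: float
    lam: float
    kappa: float      # margin of the reference solution w*
    l1_star: float    # |w*|₁
    l2_star: float    # ‖w*‖₂
    q: float          # max fraction of low inputs across patterns
    N: int

    def __post_init__(self):
        if self.kappa < 0 or not (0.0 <= self.q <= 1.0):
            raise ValueError("kappa must be >= 0 and q in [0, 1]")
        if self.l1_star <= 0 or self.l2_star <= 0:
            raise ValueError("norms of w* must be positive")
        if self.epsilon <= 0 or self.N < 1:
            raise ValueError("epsilon and N must be positive")


@dataclass
class BoundReport:
    a_lower_bound: float   # bound on the cosine a(m) at the given m
    guaranteed: bool       # slope factor positive => convergence guaranteed
    m_star: int | None     # smallest m at which the bound exceeds 1


def _slope_terms(p: ConvergenceParams) -> tuple[float, float]:
    eps, lam, q = p.epsilon, p.lam, p.q
    poly = 1.0 + 2.0 * lam * q + lam ** 2 * q
    S = (p.kappa / np.sqrt(p.N) - lam * p.l1_star / p.N
         - 0.5 * eps * poly - q * eps * (1.0 + lam) ** 2)
    D = 2.0 * p.theta / np.sqrt(p.N) + eps * poly + 2.0 * q * eps * (1.0 + lam) ** 2
    return S, D


def convergence_bound(p: ConvergenceParams, m: int) -> BoundReport:
    """Evaluate the cosine lower bound after m plasticity events."""
    if m < 0:
        raise ValueError("m must be non-negative")
    S, D = _slope_terms(p)
    value = np.sqrt(p.epsilon * m * p.N) * S / (p.l2_star * np.sqrt(D))
    guaranteed = S > 0
    m_star = None
    if guaranteed:
        m_star = int(np.ceil(p.l2_star ** 2 * D / (p.epsilon * p.N * S ** 2)))
    return BoundReport(float(value), guaranteed, m_star)


def balanced_epsilon_max(kappa: float, N: int, q: float) -> float:
    """Largest learning rate with guaranteed balanced (λ=0) convergence,
    ε = 2κ/[√N(1+2q)]."""
    return 2.0 * kappa / (np.sqrt(N) * (1.0 + 2.0 * q))


def max_low_fraction(patterns: PatternSet) -> float:
    """q = max_k (fraction of low inputs in pattern k)."""
    return float((~patterns.high_mask()).mean(axis=1).max())


def lambda_max_empirical(patterns: PatternSet, cfg: PlasticityConfig,
                         lambda_grid: np.ndarray,
                         lure_factor: int = 1,
                         seed: int | None = None
                         ) -> tuple[float | None, pd.DataFrame]:
    """Train at each λ of an ascending grid; return λ_max and the S(λ) curve.

    Uses the stop-learning rule variant.  Training stops at the first λ
    whose dynamics fails to converge within ``cfg.max_epochs``; λ_max is
    the largest converged grid point (None if even the first fails).
    Efficiency is measured with ``lure_factor``·K fresh lures per point.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) < 0) or np.any((lambda_grid < 0) | (lambda_grid > 1)):
        raise ValueError("lambda_grid must be ascending within [0, 1]")
    ss = np.random.SeedSequence(seed)
    rows = []
    lam_max = None
    for lam, child in zip(lambda_grid, ss.spawn(lambda_grid.size)):
        s1, s2 = (int(c.generate_state(1)[0] >> 1) for c in child.spawn(2))
        run_cfg = replace(cfg, lam=float(lam), rule_variant="stop_all", seed=s1)
        result = train_online(patterns, run_cfg)
        row = {"lambda": float(lam), "converged": result.converged,
               "epochs": result.epochs, "S": np.nan}
        if result.converged:
            lam_max = float(lam)
            w = result.state.w
            lures = gen_lures(patterns, lure_factor * patterns.K, seed=s2)
            p10, p01 = error_rates(w, patterns, lures, theta=cfg.theta)
            C = information(p01, p10, patterns.K, patterns.N)
            F, _ = count_functional(w, patterns, lures, theta=cfg.theta,
                                    mode="threshold")
            row["S"] = efficiency(C, F) if (F > 0 or C == 0) else np.nan
        rows.append(row)
        if not result.converged:
            break
    return lam_max, pd.DataFrame(rows)


def find_lambda_max(patterns: PatternSet, cfg: PlasticityConfig,
                    resolution: float = 1e-2, coarse_step: float = 0.1,
                    seed: int | None = None) -> float | None:
    """Coarse-to-fine bisection estimate of λ_max at resolution 10⁻².

    The per-λ epoch budget (``cfg.max_epochs``) is part of the definition
    of "no longer converges".
    """
    ss = np.random.SeedSequence(seed)

    def converges(lam: float) -> bool:
        s = int(ss.generate_state(1)[0] >> 1) ^ int(lam * 10_000)
        res = train_online(patterns, replace(cfg, lam=lam,
                                             rule_variant="stop_all", seed=s))
        return res.converged

    lo = 0.0
    if not converges(lo):
        return None
    hi = None
    lam = coarse_step
    while lam <= 1.0 + 1e-12:
        if converges(min(lam, 1.0)):
            lo = min(lam, 1.0)
        else:
            hi = min(lam, 1.0)
            break
        lam += coarse_step
    if hi is None:
        return lo
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if converges(mid):
            lo = mid
        else:
            hi = mid
    return lo


def exhaustive_testing_gain(p01: float = 0.5) -> float:
    """Relative information gain of exhaustive over paired lure testing.

    Testing with all possible lures yields K·log₂(1/p01) bits in the
    small-K limit, versus 2K·I_pair bits for equiprobable paired testing
    where I_pair = 1 − ½[(1+p01)log₂(1+p01) − p01·log₂ p01].  At
    p01 = 1/2 the excess is ≈ 60.6%.
    """
    if not (0.0 < p01 < 1.0):
        raise ValueError("p01 must lie strictly in (0, 1)")
    i_pair = 1.0 - 0.5 * ((1.0 + p01) * np.log2(1.0 + p01)
                          - p01 * np.log2(p01))
    exhaustive = np.log2(1.0 / p01)
    return float(exhaustive / (2.0 * i_pair) - 1.0)
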