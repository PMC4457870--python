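"""Offline reference solutions and post-hoc pruning.

All solvers operate on the feasibility cone of the recognition task,

    X w ≥ θ√N · 1,   w ≥ 0,

where the rows of X are the K stored patterns.

``solve_min_l1`` finds the feasible weight vector of minimal linear norm
|w|₁ — equivalent to online learning at the maximal imbalance λ_max, since
the imbalance acts as an L1 penalty.  Implemented with the HiGHS linear
programming solver.

``solve_min_l2`` finds the feasible vector of minimal Euclidean norm,
i.e. the maximal-stability (maximal-information) configuration.  scipy
ships no dedicated QP solver, so we maximise the smooth concave dual

    g(μ) = bᵀμ − ½‖[Xᵀμ]₊‖²,   μ ≥ 0,

with L-BFGS-B; the primal weights are recovered as w = [Xᵀμ]₊, which makes
the silent synapses exactly zero.

``train_minover`` is the Krauth–Mézard min-over batch rule with
rectification: at each step only the pattern with the smallest
postsynaptic sum is learned.  Its normalised stabilities converge to the
min-L2 solution's.

``prune_smallest`` / ``prune_random`` are the post-hoc deletion controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize

from .patterns import PatternSet
from .plasticity import PlasticityConfig

__all__ = [
    "SolverSolution",
    "solve_min_l1",
    "solve_min_l2",
    "train_minover",
    "prune_smallest",
    "prune_random",
]

#: relative feasibility tolerance on the pattern constraints
FEASIBILITY_RTOL = 1e-6


@dataclass
class SolverSolution:
    """A solver's weight vector with its objective and diagnostics.

    ``stabilities`` holds Δ_k = (Σ_i w_i x_i^k)/‖w‖₂, the per-pattern
    margins normalised by the Euclidean weight norm.
    """

    w: np.ndarray | None
    objective: float
    stabilities: np.ndarray | None
    status: str  # optimal | infeasible | numerical_failure
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _stabilities(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(w)
    return X @ w / nrm if nrm > 0 else X @ w


def _require_signed(patterns: PatternSet) -> None:
    if patterns.coding == "binary01":
        raise ValueError("solvers operate on bipolar or zero-mean codings")


def solve_min_l1(patterns: PatternSet, theta: float = 1.0) -> SolverSolution:
    """Minimise |w|₁ subject to X w ≥ θ√N and w ≥ 0 (HiGHS LP)."""
    _require_signed(patterns)
    X = patterns.data
    K, N = X.shape
    b = theta * np.sqrt(N)
    res = linprog(np.ones(N), A_ub=-X, b_ub=-np.full(K, b),
                  bounds=(0, None), method="highs")
    meta = {"solver": "linprog-highs", "theta": theta, "raw_status": res.status}
    if res.status == 2:
        return SolverSolution(None, np.inf, None, "infeasible", meta)
    if res.status != 0:
        return SolverSolution(None, np.nan, None, "numerical_failure", meta)
    w = np.maximum(res.x, 0.0)
    return SolverSolution(w, float(w.sum()), _stabilities(w, X), "optimal", meta)


def solve_min_l2(patterns: PatternSet, theta: float = 1.0,
                 gtol: float = 1e-10, maxiter: int = 50_000) -> SolverSolution:
    """Minimise ‖w‖₂² subject to X w ≥ θ√N and w ≥ 0 (dual L-BFGS-B).

    The objective stored is ‖w‖₂².  By cone homogeneity, scaling θ → cθ
    scales the solution w → cw exactly.
    """
    _require_signed(patterns)
    X = patterns.data
    K, N = X.shape
    b = theta * np.sqrt(N)
    bvec = np.full(K, b)

    def neg_dual(mu):
        w = np.maximum(X.T @ mu, 0.0)
        return -(bvec @ mu - 0.5 * w @ w), -(bvec - X @ w)

    res = minimize(neg_dual, np.full(K, b / N), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * K,
                   options={"maxiter": maxiter, "ftol": 1e-18, "gtol": gtol})
    w = np.maximum(X.T @ res.x, 0.0)
    meta = {"solver": "dual-lbfgsb", "theta": theta, "iterations": res.nit,
            "feasibility_rtol": FEASIBILITY_RTOL}
    min_resp = (X @ w).min() if w.any() else 0.0
    if 0.0 < min_resp < b and b - min_resp <= 1e-3 * b:
        # polish: a tiny radial scale-up restores exact feasibility at a
        # quadratically small cost in the objective
        w = w * (b / min_resp)
        meta["polish_scale"] = b / min_resp
    violation = b - (X @ w).min() if w.any() else b
    if violation > FEASIBILITY_RTOL * max(b, 1.0):
        # dual unbounded ⇒ primal infeasible; confirm with a feasibility LP
        feas = linprog(np.zeros(N), A_ub=-X, b_ub=-bvec, bounds=(0, None),
                       method="highs")
        status = "infeasible" if feas.status == 2 else "numerical_failure"
        return SolverSolution(None, np.inf if status == "infeasible" else np.nan,
                              None, status, meta)
    return SolverSolution(w, float(w @ w), _stabilities(w, X), "optimal", meta)


def train_minover(patterns: PatternSet, cfg: PlasticityConfig,
                  iterations: int = 100_000,
                  stall: int | None = None) -> SolverSolution:
    """Krauth–Mézard min-over learning with rectification.

    Requires the balanced rule (λ = 0).  Each step finds the pattern with
    the minimal postsynaptic sum, applies the balanced update to it, and
    rectifies.  Runs for the full iteration budget; optionally stops early
    when the normalised minimal stability has not improved for ``stall``
    iterations (off by default — the early dynamics can plateau for long
    stretches before the direction settles).
    """
    _require_signed(patterns)
    if cfg.lam != 0.0:
        raise ValueError("min-over requires the balanced rule (lam = 0)")
    X = patterns.data
    K, N = X.shape
    eps = cfg.epsilon
    w = np.zeros(N)
    sums = np.zeros(K)  # X @ w, maintained incrementally
    best = -np.inf
    since_best = 0
    for it in range(iterations):
        k = int(np.argmin(sums))
        delta = np.maximum(-w, eps * X[k])
        w = w + delta
        sums = sums + X @ delta
        nrm = np.linalg.norm(w)
        stab = sums[k] / nrm if nrm > 0 else -np.inf
        if stab > best + 1e-12:
            best, since_best = stab, 0
        elif stall is not None:
            since_best += 1
            if since_best >= stall:
                break
    return SolverSolution(w, float(w @ w), _stabilities(w, X), "optimal",
                          {"solver": "minover", "iterations": it + 1,
                           "min_stability": best})


def _positive_indices(w: np.ndarray) -> np.ndarray:
    return np.flatnonzero(w > 0)


def prune_smallest(w: np.ndarray, n_delete: int) -> np.ndarray:
    """Zero out the ``n_delete`` smallest strictly-positive weights."""
    w = np.asarray(w, dtype=float)
    pos = _positive_indices(w)
    if not (0 <= n_delete <= pos.size):
        raise ValueError("n_delete must not exceed the number of non-zero weights")
    out = w.copy()
    if n_delete:
        order = pos[np.argsort(w[pos], kind="stable")]
        out[order[:n_delete]] = 0.0
    return out


def prune_random(w: np.ndarray, n_delete: int,
                 seed: int | None = None) -> np.ndarray:
    """Zero out a uniform random subset of the strictly-positive weights."""
    w = np.asarray(w, dtype=float)
    pos = _positive_indices(w)
    if not (0 <= n_delete <= pos.size):
        raise ValueError("n_delete must not exceed the number of non-zero weights")
    out = w.copy()
    if n_delete:
        rng = np.random.default_rng(seed)
        out[rng.choice(pos, size=n_delete, replace=False)] = 0.0
    return out
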