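"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the LP oracle
enumerates polytope vertices, the QP oracle enumerates active sets, the
mutual information oracle sums the joint distribution term by term, and
the compressed-exponential sampler uses the Gamma transform.
"""

from __future__ import annotations

import itertools

import numpy as np


def lp_min_l1_oracle(X: np.ndarray, b: float) -> float | None:
    """Minimal Σw over {w: Xw ≥ b, w ≥ 0} by vertex enumeration.

    A vertex is the solution of N linearly independent active constraints
    drawn from the K pattern rows and the N coordinate bounds.  Returns
    None when no feasible vertex exists (infeasible or unbounded-feasible
    never happens here: the objective is bounded below by 0 on the cone).
    """
    K, N = X.shape
    A = np.vstack([X, np.eye(N)])
    rhs = np.concatenate([np.full(K, b), np.zeros(N)])
    best = None
    for combo in itertools.combinations(range(K + N), N):
        sub = A[list(combo)]
        if np.linalg.matrix_rank(sub) < N:
            continue
        try:
            w = np.linalg.solve(sub, rhs[list(combo)])
        except np.linalg.LinAlgError:
            continue
        if np.all(A @ w >= rhs - 1e-9):
            obj = float(w.sum())
            if best is None or obj < best:
                best = obj
    return best


def qp_min_l2_oracle(X: np.ndarray, b: float) -> float | None:
    """Minimal ‖w‖₂² over the same cone by active-set enumeration.

    For every subset of constraints treated as equalities, the candidate
    is the least-norm solution of the equality system; feasible candidates
    are collected and the smallest objective returned.
    """
    K, N = X.shape
    A = np.vstack([X, np.eye(N)])
    rhs = np.concatenate([np.full(K, b), np.zeros(N)])
    best = None
    for r in range(K + N + 1):
        for combo in itertools.combinations(range(K + N), r):
            if r == 0:
                w = np.zeros(N)
            else:
                sub, sub_rhs = A[list(combo)], rhs[list(combo)]
                w, *_ = np.linalg.lstsq(sub, sub_rhs, rcond=None)
                if not np.allclose(sub @ w, sub_rhs, atol=1e-9):
                    continue  # inconsistent equality system
            if np.all(A @ w >= rhs - 1e-9):
                obj = float(w @ w)
                if best is None or obj < best:
                    best = obj
    return best


def mutual_information_oracle(p01: float, p10: float) -> float:
    """I(class; response) in bits for equiprobable pattern/lure trials,
    summed directly over the 2×2 joint distribution."""
    joint = 0.5 * np.array([[p10, 1.0 - p10],     # class = pattern
                            [1.0 - p01, p01]])    # class = lure
    p_r = joint.sum(axis=0)
    p_x = joint.sum(axis=1)
    info = 0.0
    for i in range(2):
        for j in range(2):
            if joint[i, j] > 0:
                info += joint[i, j] * np.log2(joint[i, j] / (p_x[i] * p_r[j]))
    return float(info)


def sample_compressed_exponential(beta: float, c: float, n: int,
                                  rng: np.random.Generator) -> np.ndarray:
    """Draw from p(w) ∝ exp(−c·w^β) on w > 0 via u = w^β ~ Gamma(1/β, 1/c)."""
    u = rng.gamma(shape=1.0 / beta, scale=1.0 / c, size=n)
    return u ** (1.0 / beta)
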