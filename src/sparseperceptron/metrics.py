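"""Performance measures for trained and solved weight configurations.

Recognition performance is probed with the stored patterns and an equal
number of never-stored lures.  With false-positive rate p01 and
false-negative rate p10, the mutual information between pattern class and
response over the 2K test trials, normalised per synapse, is

    C = (2K/N) · I(class; response)      [bits per synapse].

When every stored pattern is recognised (p10 = 0) this reduces to the
closed form

    C = (2K/N) · (1 − ½[(1+p01)log₂(1+p01) − p01·log₂ p01]).

The memory efficiency S = C/F divides the information by the fraction F
of non-zero (functional) synapses: bits per functional synapse, an
energy-aware capacity measure.

Counting F is done by the information-drop procedure: remove the weakest
synapses one by one while probing with a large lure set, until the
empirical information drops; synapses removable without any information
loss are counted as silent.  A fast fallback counts weights below a small
relative threshold.

The false-positive rate also has a Gaussian closed form: a lure's current
is a sum of many weakly dependent terms, so for bipolar inputs

    p01 ≈ ½·erfc( θ√N / (√2·‖w‖₂) ),

with coding-level corrections for 0/1 inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfc, gammaln

from .patterns import NoiseSpec, PatternSet, corrupt_patterns
from .plasticity import SynapticState, firing_threshold

__all__ = [
    "MetricsReport",
    "CompressedExpFit",
    "WeightHistogram",
    "error_rates",
    "information",
    "information_closed_form",
    "efficiency",
    "fp_rate_analytic",
    "count_functional",
    "normalize_to_unit_threshold",
    "fit_compressed_exponential",
    "optimize_threshold",
    "report",
]


@dataclass
class MetricsReport:
    """All performance numbers for one weight configuration."""

    p01: float
    p10: float
    C: float
    F: float
    S: float
    l1: float
    l2: float
    theta_used: float


def _state_for(w: np.ndarray, patterns: PatternSet, theta: float,
               adaptive: bool = True) -> SynapticState:
    return SynapticState(np.asarray(w, dtype=float), theta=theta,
                         f=patterns.f, coding=patterns.coding,
                         adaptive=adaptive)


def _fire_tol(T: float) -> float:
    """Numerical slack for the firing test h ≥ 0.

    Offline solutions leave many pattern constraints binding *exactly* at
    the threshold, where representation error of order the solver
    tolerance would otherwise flip a coin per pattern.
    """
    return 1e-6 * max(abs(T), 1.0)


def _currents(w: np.ndarray, pset: PatternSet, theta: float,
              adaptive: bool = True) -> np.ndarray:
    state = _state_for(w, pset, theta, adaptive)
    T = firing_threshold(state)
    return pset.data @ state.w - T + _fire_tol(T)


def error_rates(w: np.ndarray, patterns: PatternSet, lures: PatternSet,
                theta: float = 1.0, sigma: float = 0.0,
                seed: int | None = None,
                adaptive: bool = True) -> tuple[float, float]:
    """Empirical (p10, p01) from one presentation of each test item.

    With σ > 0 a fresh zero-mean Gaussian is added to the current of every
    presentation.
    """
    if patterns.K == 0 or lures.K == 0:
        raise ValueError("test sets must be non-empty")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    h_p = _currents(w, patterns, theta, adaptive)
    h_l = _currents(w, lures, theta, adaptive)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        h_p = h_p + rng.normal(0.0, sigma, h_p.size)
        h_l = h_l + rng.normal(0.0, sigma, h_l.size)
    p10 = float(np.mean(h_p < 0))
    p01 = float(np.mean(h_l >= 0))
    return p10, p01


def _xlog2x(p: np.ndarray | float) -> np.ndarray | float:
    """p·log₂p with the 0·log0 = 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = p[mask] * np.log2(p[mask])
    return out if out.ndim else float(out)


def information_closed_form(p01: float, K: int, N: int) -> float:
    """C for perfect recall (p10 = 0) as a function of p01 alone."""
    if not (0.0 <= p01 <= 1.0):
        raise ValueError("p01 must lie in [0, 1]")
    per_trial = 1.0 - 0.5 * (_xlog2x(1.0 + p01) - _xlog2x(p01))
    return 2.0 * K / N * float(per_trial)


def information(p01: float, p10: float, K: int, N: int) -> float:
    """Mutual information C in bits per synapse over 2K equiprobable trials.

    Stored patterns and lures are presented with equal probability; the
    binary response carries I(class; response) bits per trial and the
    total is normalised per synapse, C = (2K/N)·I.
    """
    if not (0.0 <= p01 <= 1.0 and 0.0 <= p10 <= 1.0):
        raise ValueError("error rates must lie in [0, 1]")
    if p10 == 0.0:
        return information_closed_form(p01, K, N)
    # joint over class x ∈ {pattern, lure} (P = 1/2 each) and response r
    fire_given = np.array([1.0 - p10, p01])  # P(fire | pattern), P(fire | lure)
    p_fire = float(fire_given.mean())
    per_trial = 0.0
    for px, pf in zip((0.5, 0.5), fire_given):
        for pr_x, pr in ((pf, p_fire), (1.0 - pf, 1.0 - p_fire)):
            if pr_x > 0 and pr > 0:
                per_trial += px * pr_x * np.log2(pr_x / pr)
    return 2.0 * K / N * max(per_trial, 0.0)


def efficiency(C: float, F: float) -> float:
    """Memory efficiency S = C/F in bits per functional synapse."""
    if not (0.0 <= F <= 1.0):
        raise ValueError("F must lie in [0, 1]")
    if F == 0.0:
        if C == 0.0:
            return 0.0
        raise ValueError("efficiency undefined: C > 0 with no functional synapses")
    return C / F


def fp_rate_analytic(w: np.ndarray, theta: float, N: int,
                     coding: str = "bipolar", f: float = 0.5) -> float:
    """Gaussian approximation of the lure false-positive rate.

    Bipolar (and, with the σ-matched threshold θ_f√N, zero-mean) inputs
    give p01 = ½·erfc(θ√N/(√2‖w‖₂)).  For 0/1 inputs under the adaptive
    threshold the lure current has mean f·|w|₁ and variance
    f‖w‖₂² − f²|w|₁²/N.  Valid when enough weights are non-zero for the
    central-limit regime (documented, not enforced).
    """
    w = np.asarray(w, dtype=float)
    l2 = float(np.linalg.norm(w))
    if coding in ("bipolar", "zeromean_f"):
        T = theta * np.sqrt(N)  # θ_f√N over σ_input cancels back to θ√N
        mu, sd = 0.0, l2
    elif coding == "binary01":
        l1 = float(w.sum())
        theta_f = theta * np.sqrt(f * (1.0 - f))
        T = f * l1 + theta_f * np.sqrt(N)  # adaptive threshold γ
        mu = f * l1
        var = f * l2 ** 2 - f ** 2 * l1 ** 2 / N
        sd = np.sqrt(max(var, 0.0))
    else:
        raise ValueError(f"unknown coding {coding!r}")
    if sd == 0.0:
        return 0.0 if T - mu > 0 else 1.0
    return 0.5 * float(erfc((T - mu) / (np.sqrt(2.0) * sd)))


def _scan_removals(w: np.ndarray, pset: PatternSet, theta: float,
                   order: np.ndarray, chunk: int = 2_000_000):
    """Firing fractions after cumulatively zeroing w[order[:j]], j = 0..P.

    Returns the fraction of rows of ``pset`` that fire at every removal
    depth.  Handles the adaptive 0/1 threshold, whose value shrinks as
    total weight is removed.
    """
    state = _state_for(w, pset, theta)
    T0 = firing_threshold(state)
    cum_w = np.concatenate([[0.0], np.cumsum(w[order])])
    if pset.coding == "binary01":
        T = T0 - pset.f * cum_w  # γ tracks the remaining total weight
    else:
        T = np.full(cum_w.size, T0)
    # tolerate solver-precision slack on constraints that bind exactly at T
    T = T - 1e-6 * max(abs(T0), 1.0)
    X = pset.data
    M = X.shape[0]
    rows_per_chunk = max(1, chunk // (order.size + 1))
    fired = np.zeros(cum_w.size)
    for start in range(0, M, rows_per_chunk):
        B = X[start:start + rows_per_chunk]
        h_full = B @ w
        removed = np.cumsum(B[:, order] * w[order], axis=1)
        h = np.concatenate([h_full[:, None], h_full[:, None] - removed], axis=1)
        fired += (h >= T[None, :]).sum(axis=0)
    return fired / M


def count_functional(w: np.ndarray, patterns: PatternSet, lures: PatternSet,
                     theta: float = 1.0, mode: str = "info_drop",
                     w_zero_rel: float = 1e-8) -> tuple[float, int]:
    """Fraction F of functional synapses and the silent count n_zero.

    ``info_drop`` removes the weakest synapses in ascending order while
    probing with the lure (and pattern) sets; a synapse counts as silent
    if removing it and all weaker ones leaves the empirical information
    unchanged, where "unchanged" means within the binomial standard error
    of the probe set.  ``threshold`` simply counts w_i below
    ``w_zero_rel``·max(w).
    """
    w = np.asarray(w, dtype=float)
    N = w.size
    n_exact = int(np.sum(w == 0))
    if mode == "threshold":
        wmax = w.max() if w.size else 0.0
        n_zero = int(np.sum(w < w_zero_rel * wmax)) if wmax > 0 else N
        return 1.0 - n_zero / N, n_zero
    if mode != "info_drop":
        raise ValueError(f"unknown mode {mode!r}")
    pos = np.flatnonzero(w > 0)
    if pos.size == 0:
        return 0.0, N
    order = pos[np.argsort(w[pos], kind="stable")]
    fp = _scan_removals(w, lures, theta, order)     # P(fire | lure), per depth
    fn = 1.0 - _scan_removals(w, patterns, theta, order)
    p01_0, p10_0 = fp[0], fn[0]
    # floor of half a count: a single fresh error already signals a drop
    se01 = max(np.sqrt(p01_0 * (1 - p01_0) / lures.K), 0.5 / lures.K)
    se10 = max(np.sqrt(p10_0 * (1 - p10_0) / patterns.K), 0.5 / patterns.K)
    dropped = (fp[1:] > p01_0 + se01) | (fn[1:] > p10_0 + se10)
    first = int(np.argmax(dropped)) if dropped.any() else dropped.size
    n_zero = n_exact + first
    return 1.0 - n_zero / N, n_zero


def normalize_to_unit_threshold(w: np.ndarray, patterns: PatternSet) -> np.ndarray:
    """Rescale so the minimal pattern response min_k Σ_i w_i x_i^k equals 1.

    Puts weight vectors from different rules on a common scale; leaves the
    support, F and histogram shape invariant.
    """
    w = np.asarray(w, dtype=float)
    r = float((patterns.data @ w).min())
    if r <= 0:
        raise RuntimeError("minimal pattern response must be positive")
    return w / r


@dataclass
class WeightHistogram:
    """Pooled positive-weight histogram with the zero mass kept separate."""

    bin_edges: np.ndarray
    counts: np.ndarray
    zero_mass: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0) or self.zero_mass < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class CompressedExpFit:
    """Maximum-likelihood fit of the density p(w) ∝ exp(−c·w^β) on w > 0."""

    c: float
    beta: float
    fit_diagnostics: dict = field(default_factory=dict)


def _profile_loglik(beta: float, samples: np.ndarray) -> float:
    """Log-likelihood at β with c profiled out analytically.

    Normalisation: ∫₀^∞ exp(−c w^β) dw = Γ(1+1/β)·c^(−1/β), and the MLE of
    c at fixed β is ĉ = n/(β·Σ w^β).
    """
    n = samples.size
    s = float(np.sum(samples ** beta))
    c_hat = n / (beta * s)
    return (n / beta * np.log(c_hat) - n * gammaln(1.0 + 1.0 / beta)
            - c_hat * s)


def fit_compressed_exponential(samples: np.ndarray,
                               beta_bounds: tuple[float, float] = (0.05, 10.0)
                               ) -> CompressedExpFit:
    """Fit (c, β) of p(w) ∝ exp(−c·w^β) by maximum likelihood.

    β = 1 is the exponential law, β = 2 the hemi-Gaussian.  c is profiled
    out in closed form and β found by a bounded 1-D search.  Intended for
    ≥ 100 positive samples.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("need at least two samples")
    if np.any(samples <= 0):
        raise ValueError("samples must be strictly positive")
    res = minimize_scalar(lambda b: -_profile_loglik(b, samples),
                          bounds=beta_bounds, method="bounded",
                          options={"xatol": 1e-6})
    beta = float(res.x)
    c = samples.size / (beta * float(np.sum(samples ** beta)))
    return CompressedExpFit(c, beta, {
        "loglik": -float(res.fun), "n": int(samples.size),
        "converged": bool(res.success)})


def optimize_threshold(w: np.ndarray, patterns: PatternSet, lures: PatternSet,
                       noise: NoiseSpec, grid: np.ndarray,
                       seed: int | None = None) -> tuple[float, float]:
    """Pick the grid threshold θ* that maximises estimated information.

    The weights are first rescaled to give a unit-size *mean* response to
    the clean stored patterns, which fixes the scale of the postsynaptic
    noise σ.  Presynaptic flips (δ01, δ10) are applied once to the stored
    patterns; lures are expected to be drawn/corrupted by the caller.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    w = np.asarray(w, dtype=float)
    mean_resp = float((patterns.data @ w).mean())
    if mean_resp > 0:
        w = w / mean_resp
    ss = np.random.SeedSequence(seed)
    test_patterns = patterns
    if not noise.trivial_flips:
        test_patterns = corrupt_patterns(
            patterns, noise, seed=int(ss.generate_state(1)[0] >> 1))
    child_seeds = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(grid.size)]
    best_theta, best_C = float(grid[0]), -np.inf
    K, N = patterns.K, patterns.N
    for theta, s in zip(grid, child_seeds):
        p10, p01 = error_rates(w, test_patterns, lures, theta=float(theta),
                               sigma=noise.sigma, seed=s)
        C = information(p01, p10, K, N)
        if C > best_C:
            best_theta, best_C = float(theta), C
    return best_theta, best_C


def report(w: np.ndarray, patterns: PatternSet, lures: PatternSet,
           theta: float = 1.0, sigma: float = 0.0, seed: int | None = None,
           count_mode: str = "info_drop") -> MetricsReport:
    """Convenience wrapper computing the full MetricsReport for one state."""
    w = np.asarray(w, dtype=float)
    p10, p01 = error_rates(w, patterns, lures, theta=theta, sigma=sigma,
                           seed=seed)
    C = information(p01, p10, patterns.K, patterns.N)
    F, _ = count_functional(w, patterns, lures, theta=theta, mode=count_mode)
    S = efficiency(C, F) if (F > 0 or C == 0) else np.nan
    return MetricsReport(p01=p01, p10=p10, C=C, F=F, S=S,
                         l1=float(np.abs(w).sum()),
                         l2=float(np.linalg.norm(w)), theta_used=theta)
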