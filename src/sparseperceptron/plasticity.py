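"""Online one-class perceptron learning with imbalanced plasticity.

A single threshold unit receives N excitatory inputs (weights w_i ≥ 0,
enforced by rectification) and fires when the postsynaptic current

    h = Σ_i w_i x_i − T

is non-negative.  For bipolar inputs the threshold is T = θ√N; for the
zero-mean coding it is T = θ_f√N with θ_f = θ·√(f(1−f)) (the threshold is
scaled with the input standard deviation, so θ_f = θ/2 at f = 1/2); for
0/1 inputs the unit uses the adaptive threshold

    γ = f·Σ_i w_i + θ_f√N,

which grows with the total weight and makes the 0/1 unit fire exactly when
the equivalent zero-mean unit does.

Learning is gated: only *stored* patterns that fail to fire trigger
plasticity.  Writing the potentiation/depression magnitudes (a, b) as a
learning rate ε = (a+b)/2 and an imbalance λ = (b−a)/(a+b), the bipolar
update below threshold is Δw_i = ε(x_i − λ) followed by rectification at
zero.  λ = 0 is the classic balanced rule; λ > 0 biases weights toward the
zero bound and acts as an online L1 penalty on the weight vector: the
``decay_when_fired`` variant (which also applies a uniform decay −ελ when
the pattern already fires) performs stochastic sub-gradient descent on

    E(w) = Σ_k [T − Σ_i w_i x_i^k]_+ + λ Σ_i w_i.

For the general coding level f the below-threshold updates are
Δw_i = ε(1−f−λ) at high inputs and Δw_i = −ε(f+λ) at low inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .patterns import PatternSet

__all__ = [
    "PlasticityConfig",
    "SynapticState",
    "TrainResult",
    "postsynaptic_current",
    "firing_threshold",
    "plasticity_step",
    "train_online",
    "energy",
]

RULE_VARIANTS = ("stop_all", "decay_when_fired")


@dataclass(frozen=True)
class PlasticityConfig:
    """Learning-rule parameters.

    ``epsilon`` is the learning rate (paper-scale default 1/N, set by the
    caller), ``lam`` the imbalance in [0, 1], ``theta`` the threshold
    parameter, ``f`` the coding level.  ``rule_variant`` selects whether
    plasticity stops entirely once a pattern fires (``stop_all``) or a
    uniform decay −ελ is still applied (``decay_when_fired``).
    """

    epsilon: float = 0.01
    lam: float = 0.0
    theta: float = 1.0
    f: float = 0.5
    rule_variant: str = "stop_all"
    max_epochs: int = 10_000
    seed: int | None = None
    #: 0/1 coding only: train under the adaptive threshold γ
    adaptive_threshold: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("imbalance lam must lie in [0, 1]")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if not (0.0 < self.f < 1.0):
            raise ValueError("coding level f must lie in (0, 1)")
        if self.rule_variant not in RULE_VARIANTS:
            raise ValueError(f"unknown rule variant {self.rule_variant!r}")

    @property
    def a(self) -> float:
        """Potentiation increment, a = ε(1−λ)."""
        return self.epsilon * (1.0 - self.lam)

    @property
    def b(self) -> float:
        """Depression increment, b = ε(1+λ)."""
        return self.epsilon * (1.0 + self.lam)

    @classmethod
    def from_ab(cls, a: float, b: float, **kwargs) -> "PlasticityConfig":
        """Build from raw potentiation/depression magnitudes."""
        if a < 0 or b < 0 or a + b == 0:
            raise ValueError("a, b must be non-negative with a + b > 0")
        eps = (a + b) / 2.0
        lam = (b - a) / (a + b)
        return cls(epsilon=eps, lam=lam, **kwargs)


@dataclass
class SynapticState:
    """Non-negative weight vector plus threshold parameters."""

    w: np.ndarray
    theta: float = 1.0
    f: float = 0.5
    coding: str = "bipolar"
    #: 0/1 coding only: use the adaptive threshold γ (True) or the fixed
    #: threshold θ√(fN) that scales with the mean input activity (False)
    adaptive: bool = True

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")

    @property
    def N(self) -> int:
        return self.w.size

    @property
    def theta_f(self) -> float:
        """Coding-adjusted threshold parameter (θ for bipolar)."""
        if self.coding == "bipolar":
            return self.theta
        # scale with the input standard deviation √(f(1−f)); θ/2 at f = 1/2
        return self.theta * np.sqrt(self.f * (1.0 - self.f))

    @property
    def gamma(self) -> float:
        """Adaptive threshold for 0/1 coding: γ = f·Σw + θ_f√N."""
        return self.f * float(self.w.sum()) + self.theta_f * np.sqrt(self.N)


def firing_threshold(state: SynapticState) -> float:
    """The value T such that the unit fires when Σ w_i x_i ≥ T."""
    if state.coding == "bipolar":
        return state.theta * np.sqrt(state.N)
    if state.coding == "zeromean_f":
        return state.theta_f * np.sqrt(state.N)
    if state.coding == "binary01":
        if state.adaptive:
            return state.gamma
        return state.theta * np.sqrt(state.f * state.N)
    raise ValueError(f"unknown coding {state.coding!r}")


def postsynaptic_current(state: SynapticState, x: np.ndarray,
                         coding: str | None = None) -> float:
    """h = Σ w_i x_i − T for a single pattern vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != state.w.shape:
        raise ValueError("pattern and weight dimensions do not match")
    if coding is not None and coding != state.coding:
        state = replace(state, coding=coding)
    return float(state.w @ x) - firing_threshold(state)


def _high_mask(x: np.ndarray, coding: str, f: float) -> np.ndarray:
    if coding == "bipolar":
        return x > 0
    if coding == "binary01":
        return x > 0.5
    return x > 0  # zeromean_f: high state is 1−f > 0


def _update(w: np.ndarray, high: np.ndarray, fired: bool,
            cfg: PlasticityConfig, coding: str) -> np.ndarray:
    """One plasticity event (in place on a copy); returns the new weights."""
    eps, lam, f = cfg.epsilon, cfg.lam, cfg.f
    if not fired:
        if coding == "bipolar":
            delta = np.where(high, eps * (1.0 - lam), -eps * (1.0 + lam))
        else:
            delta = np.where(high, eps * (1.0 - f - lam), -eps * (f + lam))
        w = w + delta
    elif cfg.rule_variant == "decay_when_fired":
        w = w - eps * lam
    else:
        return w.copy()
    return np.maximum(w, 0.0)


def plasticity_step(state: SynapticState, x: np.ndarray,
                    cfg: PlasticityConfig) -> SynapticState:
    """Present one stored pattern and apply the learning rule once.

    Returns a new state; the input state is untouched.  The update is
    applied when the unit fails to fire (h < 0); rectification at zero
    follows every change, Δw_i = max{−w_i, ε·η_i}.
    """
    x = np.asarray(x, dtype=float)
    h = postsynaptic_current(state, x)
    high = _high_mask(x, state.coding, state.f)
    w = _update(state.w, high, h >= 0, cfg, state.coding)
    return replace(state, w=w)


@dataclass
class TrainResult:
    state: SynapticState
    converged: bool
    epochs: int
    updates: int  # plasticity events with h < 0


def _probe_all(w: np.ndarray, X: np.ndarray, state: SynapticState) -> np.ndarray:
    s = replace(state, w=w)
    return X @ w - firing_threshold(s)


def train_online(patterns: PatternSet, cfg: PlasticityConfig,
                 w0: np.ndarray | None = None) -> TrainResult:
    """Cycle through the stored patterns until all of them fire.

    Starts from the tabula-rasa state w = 0 (or ``w0``), presents the
    patterns in a freshly drawn random order every epoch, and stops when a
    no-plasticity probe pass fires for every pattern, or at
    ``cfg.max_epochs``.  Non-convergence is reported, not raised.
    """
    X = patterns.data
    K, N = X.shape
    rng = np.random.default_rng(cfg.seed)
    w = np.zeros(N) if w0 is None else np.array(w0, dtype=float)
    state = SynapticState(w, theta=cfg.theta, f=cfg.f, coding=patterns.coding,
                          adaptive=cfg.adaptive_threshold)
    high = _high_mask(X, patterns.coding, cfg.f)
    updates = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(K)
        for k in order:
            s = replace(state, w=w)
            h = float(w @ X[k]) - firing_threshold(s)
            if h < 0:
                updates += 1
            w = _update(w, high[k], h >= 0, cfg, patterns.coding)
        if np.all(_probe_all(w, X, state) >= 0):
            return TrainResult(replace(state, w=w), True, epoch, updates)
    return TrainResult(replace(state, w=w), False, cfg.max_epochs, updates)


def energy(state: SynapticState, patterns: PatternSet, lam: float) -> float:
    """E = Σ_k [T − Σ_i w_i x_i^k]_+ + λ·Σ_i w_i.

    The first term penalises patterns that do not yet fire; the second is
    the L1 regulariser the imbalance implements.
    """
    T = firing_threshold(state)
    margins = T - patterns.data @ state.w
    return float(np.maximum(margins, 0.0).sum() + lam * state.w.sum())
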