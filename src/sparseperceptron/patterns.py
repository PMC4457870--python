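"""Synthetic input patterns for one-class recognition memory.

The stored memories are K binary activity patterns over N presynaptic
inputs.  Three codings are supported:

``bipolar``
    x_i ∈ {−1, +1}, each high with probability 1/2 (the classic
    sign-constrained perceptron setting).
``binary01``
    x_i ∈ {0, 1}, high with probability f (the coding level).
``zeromean_f``
    z_i ∈ {−f, 1−f}, high (1−f) with probability f, so ⟨z⟩ = 0.  This is
    the mean-subtracted version of ``binary01``: x = z + f.

Correlated patterns are drawn from a template model: a random bipolar
template x̂ is fixed, and each pattern entry copies the template with
probability (1+g)/2.  In the *homogeneous* variant both x̂ and −x̂ serve as
templates (a fair coin per pattern), so every input keeps mean activity
1/2; the *heterogeneous* variant uses the single template x̂, which makes
some inputs systematically more active than others as g grows.

Presynaptic noise flips high entries to low with probability δ10 and low
entries to high with probability δ01; postsynaptic noise (σ) is handled by
the metrics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PatternSet",
    "NoiseSpec",
    "gen_patterns",
    "gen_correlated",
    "corrupt_patterns",
    "gen_lures",
]

CODINGS = ("bipolar", "binary01", "zeromean_f")
CORRELATION_MODES = ("none", "homogeneous", "heterogeneous")


def _high_low(coding: str, f: float) -> tuple[float, float]:
    """(high, low) entry values for a coding."""
    if coding == "bipolar":
        return 1.0, -1.0
    if coding == "binary01":
        return 1.0, 0.0
    if coding == "zeromean_f":
        return 1.0 - f, -f
    raise ValueError(f"unknown coding {coding!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Presynaptic flip probabilities and postsynaptic current noise s.d."""

    delta01: float = 0.0
    delta10: float = 0.0
    sigma: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.delta01 <= 1.0 and 0.0 <= self.delta10 <= 1.0):
            raise ValueError("flip probabilities must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def trivial_flips(self) -> bool:
        return self.delta01 == 0.0 and self.delta10 == 0.0


@dataclass
class PatternSet:
    """A K×N matrix of input patterns plus its generative metadata.

    The metadata (coding, f, g, correlation mode, templates, seed) is what
    lure generation needs to draw fresh patterns *from the same law* as the
    stored set.
    """

    data: np.ndarray
    coding: str = "bipolar"
    f: float = 0.5
    g: float = 0.0
    correlation_mode: str = "none"
    templates: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < 1:
            raise ValueError("data must be a K×N matrix with K, N >= 1")
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.correlation_mode not in CORRELATION_MODES:
            raise ValueError(f"unknown correlation mode {self.correlation_mode!r}")
        hi, lo = _high_low(self.coding, self.f)
        if not np.all(np.isin(self.data, [hi, lo])):
            raise ValueError(f"entries must lie in {{{lo}, {hi}}} for {self.coding}")
        if self.correlation_mode == "homogeneous":
            t = self.templates
            if t is None or t.shape[0] != 2 or not np.array_equal(t[0], -t[1]):
                raise ValueError("homogeneous mode needs two opposite templates")
        if self.correlation_mode == "heterogeneous":
            if self.templates is None or self.templates.shape[0] != 1:
                raise ValueError("heterogeneous mode needs exactly one template")

    @property
    def K(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[1]

    @property
    def high_value(self) -> float:
        return _high_low(self.coding, self.f)[0]

    @property
    def low_value(self) -> float:
        return _high_low(self.coding, self.f)[1]

    def high_mask(self) -> np.ndarray:
        return self.data == self.high_value


def _check_dims(N: int, K: int) -> None:
    if N < 1 or K < 1:
        raise ValueError("N and K must be positive")


def gen_patterns(N: int, K: int, coding: str = "bipolar", f: float = 0.5,
                 seed: int | None = None) -> PatternSet:
    """Draw K i.i.d. patterns over N inputs.

    Entries are independent; the high state is drawn with probability ``f``
    (fixed at 1/2 for bipolar coding).  Deterministic for a fixed seed.
    """
    _check_dims(N, K)
    if not (0.0 < f < 1.0):
        raise ValueError("coding level f must lie strictly in (0, 1)")
    if coding == "bipolar" and f != 0.5:
        raise ValueError("bipolar coding fixes f = 1/2")
    hi, lo = _high_low(coding, f)
    rng = np.random.default_rng(seed)
    data = np.where(rng.random((K, N)) < f, hi, lo)
    return PatternSet(data, coding=coding, f=f, seed=seed)


def gen_correlated(N: int, K: int, g: float, mode: str = "homogeneous",
                   seed: int | None = None) -> PatternSet:
    """Draw K correlated bipolar patterns from the template model.

    Each entry copies its template with probability (1+g)/2.  In
    ``homogeneous`` mode each pattern first picks x̂ or −x̂ with a fair
    coin; ``heterogeneous`` mode always uses x̂.  g = 0 recovers
    ``gen_patterns``; g = 1 makes every pattern a copy (or reversal) of the
    template.
    """
    _check_dims(N, K)
    if not (0.0 <= g <= 1.0):
        raise ValueError("correlation parameter g must lie in [0, 1]")
    if mode not in ("homogeneous", "heterogeneous"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    rng = np.random.default_rng(seed)
    template = np.where(rng.random(N) < 0.5, 1.0, -1.0)
    if mode == "homogeneous":
        signs = np.where(rng.random(K) < 0.5, 1.0, -1.0)
        base = signs[:, None] * template[None, :]
        templates = np.stack([template, -template])
    else:
        base = np.broadcast_to(template, (K, N)).copy()
        templates = template[None, :]
    keep = rng.random((K, N)) < (1.0 + g) / 2.0
    data = np.where(keep, base, -base)
    return PatternSet(data, coding="bipolar", f=0.5, g=g,
                      correlation_mode=mode, templates=templates, seed=seed)


def _flip(data: np.ndarray, hi: float, lo: float, noise: NoiseSpec,
          rng: np.random.Generator) -> np.ndarray:
    u = rng.random(data.shape)
    high = data == hi
    out = data.copy()
    out[high & (u < noise.delta10)] = lo
    out[~high & (u < noise.delta01)] = hi
    return out


def corrupt_patterns(p: PatternSet, noise: NoiseSpec,
                     seed: int | None = None) -> PatternSet:
    """Apply state-conditional flips (δ10 high→low, δ01 low→high).

    Pure function: the input set is untouched.  Bipolar and zero-mean
    codings are handled by mapping the high/low states.
    """
    rng = np.random.default_rng(seed)
    hi, lo = _high_low(p.coding, p.f)
    data = _flip(p.data, hi, lo, noise, rng)
    return replace(p, data=data, templates=None if p.templates is None
                   else p.templates.copy())


def gen_lures(reference: PatternSet, M: int, noise: NoiseSpec | None = None,
              seed: int | None = None) -> PatternSet:
    """Draw M lure patterns from the same generative law as ``reference``.

    Correlated references reuse their stored templates; with non-trivial
    presynaptic noise the lures are corrupted the same way as test
    patterns, which matches their mean activity to
    ⟨x⟩ = (1−f)δ01 + f(1−δ10) in the i.i.d. case.
    """
    if M < 1:
        raise ValueError("M must be positive")
    rng = np.random.default_rng(seed)
    N = reference.N
    if reference.correlation_mode != "none":
        if reference.templates is None:
            raise RuntimeError("correlated reference is missing its templates")
        template = reference.templates[0]
        if reference.correlation_mode == "homogeneous":
            signs = np.where(rng.random(M) < 0.5, 1.0, -1.0)
            base = signs[:, None] * template[None, :]
        else:
            base = np.broadcast_to(template, (M, N)).copy()
        keep = rng.random((M, N)) < (1.0 + reference.g) / 2.0
        data = np.where(keep, base, -base)
    else:
        hi, lo = _high_low(reference.coding, reference.f)
        data = np.where(rng.random((M, N)) < reference.f, hi, lo)
    lures = replace(reference, data=data,
                    templates=None if reference.templates is None
                    else reference.templates.copy())
    if noise is not None and not noise.trivial_flips:
        hi, lo = _high_low(lures.coding, lures.f)
        lures.data = _flip(lures.data, hi, lo, noise, rng)
    return lures
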