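# Methods

## Model

A single threshold unit receives N excitatory inputs with weights
w_i ≥ 0 and fires when the postsynaptic current

    h = Σ_i w_i x_i − T

is non-negative. It must learn to fire for each of K stored binary
patterns (memory load α = K/N) while staying silent for lures — random
patterns drawn from the same law as the stored set. Only stored patterns
trigger plasticity (one-class learning); lures never do. Non-negativity
is enforced by rectifying every weight change at zero, so the full
update is Δw_i = max{−w_i, ε·η_i}.

Three input codings are supported, with the threshold T chosen per
coding:

| coding      | entries        | high prob. | threshold T                  |
|-------------|----------------|------------|------------------------------|
| bipolar     | {−1, +1}       | 1/2        | θ√N                          |
| zeromean_f  | {−f, 1−f}      | f          | θ_f√N, θ_f = θ·√(f(1−f))     |
| binary01    | {0, 1}         | f          | γ = f·Σ_i w_i + θ_f√N        |

The source model prints no θ_f scaling rule for f ≠ 1/2; we scale the
threshold with the input standard deviation √(f(1−f)), which equals 1/2
at f = 1/2. This choice makes the f = 1/2 zero-mean model reproduce the
bipolar model *exactly* (trajectory for trajectory, see below), which is
the property the generalisation is meant to preserve.

The adaptive threshold γ for 0/1 inputs grows with the total weight
during learning — a homeostatic excitability adjustment. It makes the
0/1 unit's fire/no-fire decision identical to the zero-mean unit's, by
the change of variables x = z + f. A fixed-threshold variant
(T = θ√(fN)) is available for comparison; its information degrades as f
approaches 1/2.

## Plasticity rules

Writing the potentiation/depression magnitudes (a, b) as a learning
rate ε = (a+b)/2 and an imbalance λ = (b−a)/(a+b) ∈ [0, 1], the
below-threshold bipolar update is

    Δw_i = ε(x_i − λ),  then rectify at 0,

and for a general coding level, Δw_i = ε(1−f−λ) at high inputs and
−ε(f+λ) at low inputs. λ = 0 balances potentiation and depression to the
input statistics; λ > 0 biases the drift towards the zero bound.

Two stop-learning variants exist. `stop_all` freezes all plasticity once
the presented pattern fires (used for the λ_max experiments).
`decay_when_fired` still applies a uniform decay −ελ after firing; this
variant performs stochastic sub-gradient descent on

    E(w) = Σ_k [T − Σ_i w_i x_i^k]_+ + λ·Σ_i w_i,

making explicit that the imbalance is an online L1 regulariser. Because
the decay never stops, the `decay_when_fired` dynamics only reaches a
stochastic equilibrium near the feasibility boundary; at moderate λ·ε
the no-plasticity convergence probe (see below) can keep failing even
though the energy is low. The probe itself never applies plasticity —
convergence means "a full pass over the stored set fires for every
pattern with the weights frozen".

Training starts from the tabula-rasa state w = 0 (optionally from a
caller-supplied w0), presents the stored patterns in a freshly drawn
random order each epoch, and counts as "updates" only presentations with
h < 0. Defaults follow the study conditions: ε = 1/N, θ = 1. Firing is
at h ≥ 0 exactly; the epoch budget (default 10⁴) is part of the
definition of non-convergence and is recorded with every λ_max estimate.

## Offline baselines

Both baselines live on the feasibility cone {w : Xw ≥ θ√N·1, w ≥ 0}.

* **Minimum linear norm** (min |w|₁): linear program, solved with HiGHS.
  Equivalent to online learning at the maximal imbalance λ_max — the
  L1 penalty dominates — and produces the sparsest solutions here.
* **Minimum Euclidean norm** (min ‖w‖₂²): the maximal-stability and
  hence maximal-information configuration (see the information section).
  scipy ships no QP solver, so we maximise the smooth concave dual
  g(μ) = bᵀμ − ½‖[Xᵀμ]₊‖² over μ ≥ 0 with L-BFGS-B and recover
  w = [Xᵀμ]₊. The projection makes silent synapses *exactly* zero. If
  the returned point under-shoots the constraints by ≤ 0.1% a radial
  rescale restores exact feasibility at quadratically small objective
  cost; a larger violation triggers a feasibility LP to distinguish an
  infeasible instance from a numerical failure. The solver was verified
  against an exhaustive active-set oracle at small N.
* **Min-over**: batch Krauth–Mézard rule with rectification — update
  only the pattern with the minimal postsynaptic sum. Its normalised
  stabilities converge to the QP solution's (measured: 2·10⁻⁴ relative
  after 2·10⁵ iterations at N = 100, α = 0.3). It runs on a fixed
  iteration budget; an optional stall window exists but is off by
  default because the early dynamics plateaus for long stretches.
* **Pruning controls**: zero the n smallest (or n random) positive
  weights after learning, with n matched to the silent count of the
  min-L1 solution on the same patterns.

Infeasibility (α > α_max instances) is reported as a status, never
raised, so capacity sweeps can count failures.

## Information and efficiency

Performance is probed with the K stored patterns and M lures presented
with equal probability. With false-positive rate p01 and false-negative
rate p10, the mutual information between pattern class and response over
the 2K trials, per synapse, is C = (2K/N)·I(class; response); at
p10 = 0 this reduces to

    C = (2K/N)·(1 − ½[(1+p01)log₂(1+p01) − p01·log₂ p01]),

with 0·log 0 ≡ 0 throughout. Memory efficiency S = C/F divides by the
fraction F of functional synapses — bits per functional synapse, the
energy-aware measure. Testing against *all* 2^N − K possible lures
instead would yield K·log₂(1/p01) bits; at p01 = 1/2 that is 60.6% more
than paired testing, computed in closed form.

A lure's current is a sum of many weakly dependent terms, so p01 has a
Gaussian closed form: ½·erfc(θ√N/(√2‖w‖₂)) for bipolar inputs (the
information depends on the weights only through ‖w‖₂, which is why the
min-L2 solution is information-optimal), and mean f|w|₁ with variance
f‖w‖₂² − f²|w|₁²/N for 0/1 inputs under the adaptive threshold.

**Counting silent synapses.** Solver output and float dust make "is this
weight zero?" ambiguous, and near λ_max the online rule matches the LP's
linear norm while keeping many tiny non-zero weights. The authoritative
count is therefore functional: remove the weakest synapses in ascending
order while probing with a large lure set (default 100·K probes) until
the empirical information drops — "drops" meaning a new false negative
or a false-positive excess beyond the binomial standard error of the
probe. A fast fallback counts weights below 10⁻⁸·max_i w_i; for LP/QP
solutions both counts agree exactly and are insensitive to the fallback
tolerance across three decades (tested). The probe tolerates a relative
slack of 10⁻⁶ on the firing condition, because offline solutions leave
many constraints binding exactly at threshold where representation error
would otherwise flip a coin per pattern; the same slack is applied in
the empirical error rates.

Weight histograms are pooled across trials after rescaling each vector
to a unit minimal pattern response (min_k Σ_i w_i x_i^k = 1), zero mass
kept separate from the positive density. The positive part of the sparse
(min-L1) distribution is fitted by maximum likelihood to the compressed
exponential p(w) ∝ exp(−c·w^β): the normalisation is
Γ(1+1/β)·c^(−1/β), c profiles out as ĉ = n/(β·Σw^β), and β is found by
a bounded 1-D search. MLE is used rather than least squares on binned
counts because the fit method in the source is unstated and MLE needs no
binning convention; parameter recovery is verified on synthetic samples
drawn via the Gamma transform (w = G^{1/β}, G ~ Gamma(1/β, 1/c)).

## Synthetic data

All inputs are generated internally; there is no external data.
Patterns are i.i.d. across entries and patterns (no fixed active count
per pattern). Correlated patterns follow a template model: a random
bipolar template x̂ is drawn once and each entry copies its template
with probability (1+g)/2. The homogeneous variant uses x̂ and −x̂ with a
fair coin per pattern (the mixing ratio is forced by symmetry), keeping
every input's mean activity at 1/2; the heterogeneous variant uses x̂
alone, making input activity rates bimodal as g grows. Lures are always
drawn from the same generative law as the stored set (same templates,
same g). Presynaptic noise flips high entries to low with probability
δ10 and low to high with δ01; noisy lures are corrupted the same way,
which matches their mean activity to ⟨x⟩ = (1−f)δ01 + f(1−δ10).
Postsynaptic noise adds a fresh zero-mean Gaussian (s.d. σ) to the
current of every presentation, with the weights first rescaled to a unit
mean response so σ has a fixed scale.

What the generator does *not* emulate: temporal structure, spiking,
natural-stimulus statistics, or correlations between the lures and the
stored set. Passing tests therefore show that the learning rules behave
as derived under the stated pattern statistics, not that they would on
structured sensory data.

Every generator takes an explicit seed and owns its RNG stream (no
global state); sweep drivers derive per-condition child seeds from a
`SeedSequence`, so any run is bit-reproducible from (config, seed).

## Convergence theory

Assuming a feasible reference w* with margin κ (Σ_i w*_i x_i^k ≥
(θ+κ)√N), tracking the cosine between w* and the learned weights over
plasticity events m yields the lower bound

    a(m) > √(εmN)·S/(‖w*‖₂√D),
    S = κ/√N − λ|w*|₁/N − ½ε(1+2λq+λ²q) − qε(1+λ)²,
    D = 2θ/√N + ε(1+2λq+λ²q) + 2qε(1+λ)²,

with q the maximal low-input fraction over the stored patterns. A
positive S guarantees convergence within m* = ‖w*‖₂²·D/(εNS²) updates
(a(m) ≤ 1 by Cauchy–Schwarz). At λ = 0 the condition S ≥ 0 is
ε ≤ 2κ/[√N(1+2q)]. For bound evaluation, κ and w* are taken from the
min-L2 solution at threshold θ+κ — the proof only needs *some* feasible
reference, and the maximal-stability configuration certifies the largest
margin. The proof's per-step bookkeeping sets are not represented; only
the closed-form bound is. The bound is loose (simulations converge far
earlier) but its sign structure carries the physics: λ_max grows with
the attainable margin and shrinks with the memory load.

λ_max is also estimated empirically, by training at increasing λ (with
the stop-learning variant) until the dynamics no longer converges within
the epoch budget; the search is a coarse ascending scan refined by
bisection to resolution 10⁻². Per-instance λ_max fluctuates at moderate
N, so cross-load comparisons average over instances and assert ordering,
not values.

## Experiment drivers and problem sizes

The workbench reproduces the figure-level sweeps (capacity, weight
histograms, coding level, correlations, noise, imbalance) at desk scale:
N = 500 with 20 trials by default, against N = 1000 in the source
study. The acceptance script uses N = 300 (20 instances per grid point)
for the capacity crossing, N = 500 (20 trials per load) for the QP
silent fraction, and 100 pooled solutions at N = 1000 for the weight
distribution exponent — sizes at which each statistic is stable to well
within its comparison tolerance. Efficiency curves in sweep output use
the threshold zero-count by default for speed; the information-drop
count is used where the silent fraction is itself the quantity of
interest.

## Known limitations

* The `decay_when_fired` variant's equilibrium (see above) means the
  convergence probe can report non-convergence at λ values the
  `stop_all` variant handles; λ_max estimates always use `stop_all`.
* The Gaussian p01 approximation assumes enough non-zero weights for
  the central-limit regime; it is documented, not enforced, and degrades
  for very sparse supports at small N.
* The 0/1-coding lure-current variance uses the annealed form
  f‖w‖₂² − f²|w|₁²/N (averaging over the weight distribution), which
  differs from the quenched per-realisation variance f(1−f)‖w‖₂² unless
  the weights are homogeneous.
* Replica-theoretic capacity limits and greedy L0 minimisation are out
  of scope, as is any fit to electrophysiological data.
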