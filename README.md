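# sparseperceptron

Energy-efficient memory in a one-class, sign-constrained perceptron:
online learning rules with **imbalanced synaptic plasticity**, their
offline optima, and the information/efficiency metrics to compare them.

## The problem

Synaptic transmission dominates the brain's energy budget, so a neuron
that stores memories with fewer active synapses stores them more
cheaply. This package studies the simplest setting where that trade-off
is sharp: a single threshold neuron with N excitatory synapses
(w_i ≥ 0) must fire for each of K stored binary patterns
(h = Σ_i w_i x_i − θ√N ≥ 0) and stay silent for random lures. Learning
is one-class — only stored patterns trigger plasticity.

Writing potentiation and depression as a = ε(1−λ), b = ε(1+λ), the
below-threshold update is

    Δw_i = ε(x_i − λ),  followed by rectification at w_i = 0.

The imbalance λ ∈ [0, 1] is the knob. λ = 0 is the classic balanced
rule; λ > 0 biases weights towards the zero bound and is equivalent to
descending the L1-regularised energy

    E(w) = Σ_k [θ√N − Σ_i w_i x_i^k]₊ + λ Σ_i w_i,

so imbalanced plasticity is an *online* sparse-coding regulariser. At
the maximal admissible imbalance λ_max(α) the learned state coincides
with the minimum-|w|₁ feasible solution (a linear program), while the
information-optimal state is the minimum-‖w‖₂ solution (a quadratic
program, ≈50% silent synapses). Performance is measured by the mutual
information per synapse C, and by the memory efficiency S = C/F — bits
per *functional* synapse, where 1−F is the silent fraction.

## Worked example

```python
from sparseperceptron import (PlasticityConfig, gen_lures, gen_patterns,
                              report, train_online)

N, K = 500, 50
patterns = gen_patterns(N, K, seed=1)
lures = gen_lures(patterns, 20 * K, seed=2)
for lam in (0.0, 0.1):
    cfg = PlasticityConfig(epsilon=1/N, lam=lam, max_epochs=5000, seed=3)
    res = train_online(patterns, cfg)
    rep = report(res.state.w, patterns, lures)
    print(lam, rep.C, 1 - rep.F, rep.S)
```

prints (see `examples/01_imbalanced_learning.py`):

```
lambda = 0.0: converged=True after 102 epochs (3086 plasticity events)
  C = 0.178 bits/synapse   silent fraction = 0.39   S = C/F = 0.293 bits/functional synapse
lambda = 0.1: converged=True after 229 epochs (7216 plasticity events)
  C = 0.175 bits/synapse   silent fraction = 0.46   S = C/F = 0.322 bits/functional synapse
```

Biasing plasticity towards depression silences more synapses at a
nearly invisible information cost (C: 0.178 → 0.175 bits/synapse), so
the information per functional synapse rises. The offline extremes
(`examples/02_offline_optima.py`) bracket the online rules: the min-|w|₁
solution reaches S ≈ 1.5 with 91% silent synapses, the min-‖w‖₂ optimum
maximises raw C with ~50% silent.

The `examples/` directory has one short script per capability: online
learning, offline LP/QP optima and min-over, the compressed-exponential
weight distribution (β ≈ 1.4), noise robustness and input correlations,
and the convergence bound / λ_max estimation. A thin CLI mirrors the
drivers: `sparseperceptron simulate|solve|sweep|fit --help`.

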