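"""Experiment drivers reproducing the study's figure-level sweeps at desk
scale.

Each driver follows the same protocol: generate synthetic patterns,
train/solve with the requested rules, measure (C, S, F, p01, p10) against
fresh lures, and collect one tidy row per condition × trial × method.
Sweeps are deterministic given (config, seed): every condition/trial gets
its own child seed from a spawned :class:`numpy.random.SeedSequence`.

Experiments
-----------
``capacity_sweep``
    C, S and 1−F versus the memory load α for balanced online learning,
    maximal imbalance (min-L1), the QP optimum, and matched thresholded /
    random pruning of the balanced solution.
``weight_hist``
    Pooled synaptic weight histograms (unit-threshold normalised) for the
    balanced, QP and min-L1 rules.
``coding_sweep``
    Information versus coding level f for 0/1 inputs under the adaptive
    threshold γ and under a fixed threshold.
``correlation_sweep``
    Efficiency versus the template correlation g, homogeneous and
    heterogeneous variants.
``noise_sweep``
    C and S versus presynaptic flip probability δ (δ01 = δ10 = δ) or
    postsynaptic noise σ, with per-solution threshold re-optimisation.
``imbalance_sweep``
    S(λ) curves up to the empirical λ_max, with the LP efficiency as
    reference.

Desk-scale defaults are N = 500 with 20 trials; the published curves used
N = 1000.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (WeightHistogram, count_functional, efficiency,
                      error_rates, information, normalize_to_unit_threshold,
                      optimize_threshold)
from .patterns import NoiseSpec, gen_correlated, gen_lures, gen_patterns
from .plasticity import PlasticityConfig, train_online
from .solvers import prune_random, prune_smallest, solve_min_l1, solve_min_l2
from .theory import lambda_max_empirical

__all__ = ["ExperimentConfig", "SweepResult", "run_sweep",
           "make_weight_histogram"]

EXPERIMENTS = ("capacity_sweep", "weight_hist", "coding_sweep",
               "correlation_sweep", "noise_sweep", "imbalance_sweep")


@dataclass
class ExperimentConfig:
    experiment: str
    N: int = 500
    trials: int = 20
    seed: int = 0
    grids: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.trials < 1 or self.N < 1:
            raise ValueError("N and trials must be positive")
        for name, grid in self.grids.items():
            if len(np.atleast_1d(grid)) == 0:
                raise ValueError(f"grid {name!r} must be non-empty")

    def grid(self, name: str, default) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.grids.get(name, default),
                                        dtype=float))


@dataclass
class SweepResult:
    table: pd.DataFrame
    provenance: dict
    artifacts: dict = field(default_factory=dict)


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] >> 1)


def _measure(w, patterns, lures, theta, count_mode="threshold"):
    p10, p01 = error_rates(w, patterns, lures, theta=theta)
    C = information(p01, p10, patterns.K, patterns.N)
    F, n_zero = count_functional(w, patterns, lures, theta=theta,
                                 mode=count_mode)
    S = efficiency(C, F) if (F > 0 or C == 0) else np.nan
    return {"C": C, "S": S, "F": F, "p01": p01, "p10": p10,
            "n_zero": n_zero, "l1": float(np.abs(w).sum()),
            "l2": float(np.linalg.norm(w))}


def _train_balanced(patterns, theta, opts, seed):
    cfg = PlasticityConfig(epsilon=opts.get("epsilon", 1.0 / patterns.N),
                           lam=0.0, theta=theta, f=patterns.f,
                           max_epochs=opts.get("max_epochs", 2_000),
                           seed=seed)
    return train_online(patterns, cfg)


def _capacity_sweep(cfg: ExperimentConfig) -> SweepResult:
    theta = cfg.options.get("theta", 1.0)
    count_mode = cfg.options.get("count_mode", "threshold")
    alphas = cfg.grid("alpha", [0.1, 0.2, 0.4, 0.6, 0.8])
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for alpha, ss_a in zip(alphas, root.spawn(alphas.size)):
        K = max(1, int(round(alpha * cfg.N)))
        for trial, ss_t in enumerate(ss_a.spawn(cfg.trials)):
            s_pat, s_lure, s_train, s_prune = map(_seed_of, ss_t.spawn(4))
            patterns = gen_patterns(cfg.N, K, seed=s_pat)
            lures = gen_lures(patterns, K, seed=s_lure)
            base = {"alpha": float(alpha), "K": K, "trial": trial}

            res = _train_balanced(patterns, theta, cfg.options, s_train)
            w_bal = res.state.w
            rows.append(base | {"method": "balanced",
                                "converged": res.converged}
                        | _measure(w_bal, patterns, lures, theta, count_mode))

            l1 = solve_min_l1(patterns, theta)
            if l1.ok:
                m_l1 = _measure(l1.w, patterns, lures, theta, count_mode)
                rows.append(base | {"method": "max_imbalance",
                                    "converged": True} | m_l1)
            qp = solve_min_l2(patterns, theta)
            if qp.ok:
                rows.append(base | {"method": "qp", "converged": True}
                            | _measure(qp.w, patterns, lures, theta,
                                       count_mode))
            if l1.ok and res.converged:
                n_bal = int(np.sum(w_bal == 0))
                n_del = max(0, m_l1["n_zero"] - n_bal)
                n_del = min(n_del, int(np.sum(w_bal > 0)))
                for method, w_pruned in (
                        ("prune_smallest", prune_smallest(w_bal, n_del)),
                        ("prune_random", prune_random(w_bal, n_del,
                                                      seed=s_prune))):
                    rows.append(base | {"method": method, "converged": True}
                                | _measure(w_pruned, patterns, lures, theta,
                                           count_mode))
    return SweepResult(pd.DataFrame(rows), _provenance(cfg))


def make_weight_histogram(solutions: list[np.ndarray],
                          bins: int = 50) -> WeightHistogram:
    """Pool positive weights of unit-threshold-normalised vectors.

    The zero mass is kept separate from the positive density; pooling is
    order-invariant.
    """
    if not solutions:
        raise ValueError("need at least one weight vector")
    pooled = np.concatenate([np.asarray(w, dtype=float).ravel()
                             for w in solutions])
    zero_mass = int(np.sum(pooled == 0))
    positive = pooled[pooled > 0]
    if positive.size:
        counts, edges = np.histogram(positive, bins=bins)
    else:
        counts, edges = np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1)
    return WeightHistogram(edges, counts, zero_mass)


def _weight_hist(cfg: ExperimentConfig) -> SweepResult:
    theta = cfg.options.get("theta", 1.0)
    alpha = float(cfg.options.get("alpha", 0.1))
    bins = int(cfg.options.get("bins", 50))
    K = max(1, int(round(alpha * cfg.N)))
    root = np.random.SeedSequence(cfg.seed)
    pools: dict[str, list[np.ndarray]] = {"balanced": [], "qp": [],
                                          "max_imbalance": []}
    rows = []
    for trial, ss_t in enumerate(root.spawn(cfg.trials)):
        s_pat, s_train = map(_seed_of, ss_t.spawn(2))
        patterns = gen_patterns(cfg.N, K, seed=s_pat)
        res = _train_balanced(patterns, theta, cfg.options, s_train)
        sols = {"balanced": res.state.w if res.converged else None,
                "qp": solve_min_l2(patterns, theta).w,
                "max_imbalance": solve_min_l1(patterns, theta).w}
        for method, w in sols.items():
            if w is None:
                continue
            w_n = normalize_to_unit_threshold(w, patterns)
            pools[method].append(w_n)
            rows.append({"trial": trial, "method": method,
                         "zero_fraction": float(np.mean(w_n == 0)),
                         "l1": float(w_n.sum())})
    artifacts = {m: make_weight_histogram(v, bins=bins)
                 for m, v in pools.items() if v}
    return SweepResult(pd.DataFrame(rows), _provenance(cfg), artifacts)


def _coding_sweep(cfg: ExperimentConfig) -> SweepResult:
    theta = cfg.options.get("theta", 1.0)
    alpha = float(cfg.options.get("alpha", 0.5))
    fs = cfg.grid("f", [0.05, 0.1, 0.25, 0.5, 0.75])
    K = max(1, int(round(alpha * cfg.N)))
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for f, ss_f in zip(fs, root.spawn(fs.size)):
        for trial, ss_t in enumerate(ss_f.spawn(cfg.trials)):
            s_pat, s_lure, s1, s2 = map(_seed_of, ss_t.spawn(4))
            patterns = gen_patterns(cfg.N, K, coding="binary01", f=float(f),
                                    seed=s_pat)
            lures = gen_lures(patterns, K, seed=s_lure)
            for label, adaptive, seed in (("adaptive", True, s1),
                                          ("fixed", False, s2)):
                run = PlasticityConfig(
                    epsilon=cfg.options.get("epsilon", 1.0 / cfg.N),
                    lam=0.0, theta=theta, f=float(f),
                    max_epochs=cfg.options.get("max_epochs", 2_000),
                    seed=seed, adaptive_threshold=adaptive)
                res = train_online(patterns, run)
                p10, p01 = error_rates(res.state.w, patterns, lures,
                                       theta=theta, adaptive=adaptive)
                rows.append({"f": float(f), "trial": trial,
                             "threshold_model": label,
                             "converged": res.converged,
                             "C": information(p01, p10, K, cfg.N),
                             "p01": p01, "p10": p10})
    return SweepResult(pd.DataFrame(rows), _provenance(cfg))


def _correlation_sweep(cfg: ExperimentConfig) -> SweepResult:
    theta = cfg.options.get("theta", 1.0)
    alpha = float(cfg.options.get("alpha", 0.1))
    count_mode = cfg.options.get("count_mode", "threshold")
    gs = cfg.grid("g", [0.0, 0.2, 0.4, 0.6, 0.8])
    modes = cfg.options.get("modes", ("homogeneous", "heterogeneous"))
    K = max(1, int(round(alpha * cfg.N)))
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for mode in modes:
        for g, ss_g in zip(gs, root.spawn(gs.size)):
            for trial, ss_t in enumerate(ss_g.spawn(cfg.trials)):
                s_pat, s_lure, s_train = map(_seed_of, ss_t.spawn(3))
                patterns = gen_correlated(cfg.N, K, float(g), mode=mode,
                                          seed=s_pat)
                lures = gen_lures(patterns, K, seed=s_lure)
                base = {"mode": mode, "g": float(g), "trial": trial}
                res = _train_balanced(patterns, theta, cfg.options, s_train)
                if res.converged:
                    rows.append(base | {"method": "balanced"}
                                | _measure(res.state.w, patterns, lures,
                                           theta, count_mode))
                for method, sol in (("max_imbalance",
                                     solve_min_l1(patterns, theta)),
                                    ("qp", solve_min_l2(patterns, theta))):
                    if sol.ok:
                        rows.append(base | {"method": method}
                                    | _measure(sol.w, patterns, lures, theta,
                                               count_mode))
    return SweepResult(pd.DataFrame(rows), _provenance(cfg))


def _noise_sweep(cfg: ExperimentConfig) -> SweepResult:
    theta = cfg.options.get("theta", 1.0)
    alpha = float(cfg.options.get("alpha", 0.1))
    f = float(cfg.options.get("f", 0.5))
    lure_factor = int(cfg.options.get("lure_factor", 100))
    deltas = cfg.grid("delta", [0.0, 0.05, 0.1, 0.2, 0.3])
    sigmas = cfg.grid("sigma", [0.0])
    theta_grid = cfg.grid("theta_grid", np.linspace(0.0, 2.0, 21))
    K = max(1, int(round(alpha * cfg.N)))
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for trial, ss_t in enumerate(root.spawn(cfg.trials)):
        s_pat, s_train, s_rest = ss_t.spawn(3)
        coding = "zeromean_f" if f != 0.5 else "bipolar"
        patterns = gen_patterns(cfg.N, K, coding=coding, f=f,
                                seed=_seed_of(s_pat))
        res = _train_balanced(patterns, theta, cfg.options,
                              _seed_of(s_train))
        l1 = solve_min_l1(patterns, theta)
        solutions = {}
        if res.converged:
            solutions["balanced"] = res.state.w
        if l1.ok:
            solutions["max_imbalance"] = l1.w
            if res.converged:
                n_del = max(0, int(np.sum(l1.w == 0))
                            - int(np.sum(res.state.w == 0)))
                n_del = min(n_del, int(np.sum(res.state.w > 0)))
                solutions["prune_smallest"] = prune_smallest(res.state.w,
                                                             n_del)
        conditions = [(float(d), float(s)) for d in deltas for s in sigmas]
        for (delta, sigma), ss_c in zip(conditions,
                                        s_rest.spawn(len(conditions))):
            noise = NoiseSpec(delta01=delta, delta10=delta, sigma=sigma)
            s_lure, s_opt = map(_seed_of, ss_c.spawn(2))
            lures = gen_lures(patterns, lure_factor * K, noise=noise,
                              seed=s_lure)
            for method, w in solutions.items():
                F = float(np.mean(w > 0))
                theta_star, C_star = optimize_threshold(
                    w, patterns, lures, noise, theta_grid, seed=s_opt)
                S = efficiency(C_star, F) if (F > 0 or C_star == 0) else np.nan
                rows.append({"trial": trial, "delta": delta, "sigma": sigma,
                             "method": method, "theta_star": theta_star,
                             "C": C_star, "S": S, "F": F})
    return SweepResult(pd.DataFrame(rows), _provenance(cfg))


def _imbalance_sweep(cfg: ExperimentConfig) -> SweepResult:
    theta = cfg.options.get("theta", 1.0)
    alphas = cfg.grid("alpha", [0.1, 0.3, 0.5])
    lam_grid = cfg.grid("lambda", np.round(np.arange(0.0, 1.0001, 0.05), 4))
    root = np.random.SeedSequence(cfg.seed)
    rows = []
    for alpha, ss_a in zip(alphas, root.spawn(alphas.size)):
        K = max(1, int(round(alpha * cfg.N)))
        for trial, ss_t in enumerate(ss_a.spawn(cfg.trials)):
            s_pat, s_sweep, s_lure = map(_seed_of, ss_t.spawn(3))
            patterns = gen_patterns(cfg.N, K, seed=s_pat)
            run = PlasticityConfig(
                epsilon=cfg.options.get("epsilon", 1.0 / cfg.N),
                lam=0.0, theta=theta,
                max_epochs=cfg.options.get("max_epochs", 2_000))
            lam_max, curve = lambda_max_empirical(patterns, run, lam_grid,
                                                  seed=s_sweep)
            l1 = solve_min_l1(patterns, theta)
            S_lp = np.nan
            if l1.ok:
                lures = gen_lures(patterns, K, seed=s_lure)
                S_lp = _measure(l1.w, patterns, lures, theta)["S"]
            for _, r in curve.iterrows():
                rows.append({"alpha": float(alpha), "trial": trial,
                             "lambda": r["lambda"], "S": r["S"],
                             "converged": bool(r["converged"]),
                             "epochs": int(r["epochs"]),
                             "lambda_max": lam_max, "S_lp": S_lp})
    return SweepResult(pd.DataFrame(rows), _provenance(cfg))


_DRIVERS = {"capacity_sweep": _capacity_sweep, "weight_hist": _weight_hist,
            "coding_sweep": _coding_sweep,
            "correlation_sweep": _correlation_sweep,
            "noise_sweep": _noise_sweep, "imbalance_sweep": _imbalance_sweep}


def _provenance(cfg: ExperimentConfig) -> dict:
    payload = dataclasses.asdict(cfg)
    payload["grids"] = {k: np.atleast_1d(np.asarray(v)).tolist()
                        for k, v in payload["grids"].items()}
    return {"config": payload, "package_version": __version__,
            "numpy_version": np.__version__}


def run_sweep(cfg: ExperimentConfig,
              out_dir: str | Path | None = None) -> SweepResult:
    """Execute one named experiment; optionally write CSV + provenance.

    Deterministic given (config, seed).  Infeasible or non-convergent
    conditions are recorded per row (or omitted for that method), never
    aborting the sweep.
    """
    result = _DRIVERS[cfg.experiment](cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.table.to_csv(out / f"{cfg.experiment}.csv", index=False)
        (out / f"{cfg.experiment}_provenance.json").write_text(
            json.dumps(result.provenance, indent=2))
        for name, hist in result.artifacts.items():
            df = pd.DataFrame({"bin_left": hist.bin_edges[:-1],
                               "bin_right": hist.bin_edges[1:],
                               "count": hist.counts})
            df.attrs["zero_mass"] = hist.zero_mass
            df.to_csv(out / f"{cfg.experiment}_{name}_hist.csv", index=False)
    return result
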