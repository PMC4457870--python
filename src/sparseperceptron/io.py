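"""Serialisation helpers: pattern sets, states and solutions to HDF5/CSV,
configs to JSON/YAML."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .patterns import PatternSet
from .plasticity import PlasticityConfig, SynapticState
from .solvers import SolverSolution

__all__ = [
    "save_patterns_hdf5", "load_patterns_hdf5", "save_patterns_csv",
    "save_state_hdf5", "load_state_hdf5",
    "save_config", "load_config",
    "save_solution_json",
]


def save_patterns_hdf5(p: PatternSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=p.data)
        d.attrs["coding"] = p.coding
        d.attrs["f"] = p.f
        d.attrs["g"] = p.g
        d.attrs["correlation_mode"] = p.correlation_mode
        if p.seed is not None:
            d.attrs["seed"] = p.seed
        if p.templates is not None:
            f.create_dataset("templates", data=p.templates)


def load_patterns_hdf5(path: str | Path) -> PatternSet:
    with h5py.File(path, "r") as f:
        d = f["data"]
        templates = f["templates"][...] if "templates" in f else None
        return PatternSet(
            d[...], coding=str(d.attrs["coding"]), f=float(d.attrs["f"]),
            g=float(d.attrs["g"]),
            correlation_mode=str(d.attrs["correlation_mode"]),
            templates=templates,
            seed=int(d.attrs["seed"]) if "seed" in d.attrs else None)


def save_patterns_csv(p: PatternSet, path: str | Path) -> None:
    """Matrix only, for quick inspection; metadata is not preserved."""
    np.savetxt(path, p.data, delimiter=",", fmt="%.17g")


def save_state_hdf5(state: SynapticState, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("w", data=state.w)
        d.attrs["theta"] = state.theta
        d.attrs["f"] = state.f
        d.attrs["coding"] = state.coding


def load_state_hdf5(path: str | Path) -> SynapticState:
    with h5py.File(path, "r") as f:
        d = f["w"]
        return SynapticState(d[...], theta=float(d.attrs["theta"]),
                             f=float(d.attrs["f"]), coding=str(d.attrs["coding"]))


def save_config(cfg: PlasticityConfig, path: str | Path) -> None:
    path = Path(path)
    payload = dataclasses.asdict(cfg)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(payload))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_config(path: str | Path) -> PlasticityConfig:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
        else json.loads(text)
    return PlasticityConfig(**payload)


def save_solution_json(sol: SolverSolution, path: str | Path) -> None:
    payload = {
        "objective": None if not np.isfinite(sol.objective) else sol.objective,
        "status": sol.status,
        "meta": sol.meta,
        "w": None if sol.w is None else sol.w.tolist(),
        "stabilities": None if sol.stabilities is None else sol.stabilities.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
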