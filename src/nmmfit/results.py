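"""Persistence of fit results: HDF5 archives and flat CSV exports."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import PARAM_NAMES, Trajectory
from .moea import FitResult

__all__ = ["save_fit_hdf5", "load_fit_hdf5", "pareto_to_csv",
           "save_trajectory_hdf5", "load_trajectory_hdf5"]


def save_trajectory_hdf5(path, traj: Trajectory) -> None:
    """Archive a simulated trajectory with its full metadata (parameters,
    integration settings, seed, sigmoid constant, noise mode)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=traj.samples)
        if traj.hi_samples is not None:
            f.create_dataset("hi_samples", data=traj.hi_samples)
        f.attrs["rate"] = traj.rate
        f.attrs["divergent"] = traj.divergent
        f.attrs["zscored"] = traj.zscored
        f.attrs["meta"] = json.dumps(traj.meta)


def load_trajectory_hdf5(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            samples=f["samples"][...],
            rate=float(f.attrs["rate"]),
            divergent=bool(f.attrs["divergent"]),
            zscored=bool(f.attrs["zscored"]),
            hi_samples=f["hi_samples"][...] if "hi_samples" in f else None,
            meta=json.loads(f.attrs["meta"]),
        )


def save_fit_hdf5(path, result: FitResult) -> None:
    """Archive the pareto set, optimum, history and provenance."""
    with h5py.File(path, "w") as f:
        front = np.array([ind.decision for ind in result.pareto_set])
        objs = np.array([ind.objectives for ind in result.pareto_set])
        f.create_dataset("pareto/decisions", data=front)
        f.create_dataset("pareto/objectives", data=objs)
        f.create_dataset("optimum/decision", data=result.optimum.decision)
        f.create_dataset("optimum/objectives", data=result.optimum.objectives)
        for key, vals in result.history.items():
            f.create_dataset(f"history/{key}", data=np.asarray(vals))
        prov = {}
        for k, v in result.provenance.items():
            if k == "initial_population":
                continue
            try:
                prov[k] = v if isinstance(v, (str, int, float)) else repr(v)
            except Exception:
                prov[k] = "<unserialisable>"
        f.attrs["provenance"] = json.dumps(prov)
        f.attrs["param_names"] = json.dumps(list(PARAM_NAMES))


def load_fit_hdf5(path) -> dict:
    """Read an archive back as plain arrays (no Individual reconstruction)."""
    with h5py.File(path, "r") as f:
        return {
            "pareto_decisions": f["pareto/decisions"][...],
            "pareto_objectives": f["pareto/objectives"][...],
            "optimum_decision": f["optimum/decision"][...],
            "optimum_objectives": f["optimum/objectives"][...],
            "history": {k: f[f"history/{k}"][...] for k in f["history"]},
            "provenance": json.loads(f.attrs["provenance"]),
        }


def pareto_to_csv(path, result: FitResult) -> None:
    """One row per non-dominated member: parameters, objectives, rank."""
    rows = []
    for ind in result.pareto_set:
        row = dict(zip(PARAM_NAMES, ind.decision))
        for i, v in enumerate(ind.objectives):
            row[f"objective_{i}"] = v
        row["rank"] = ind.rank
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
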