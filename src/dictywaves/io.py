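"""Trajectory and summary persistence (HDF5 containers, CSV series)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .lattice import PopulationLattice
from .params import ModelParams

__all__ = ["save_trajectory", "load_trajectory", "series_frame", "save_series_csv"]


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory to an HDF5 container.

    Layout: ``/series/{iterations,ubar,sigma,cov}``, optional
    ``/snapshots/{iterations,u,v}``, ``/lattice/type_map``; the full
    parameter set, lattice provenance and run metadata are stored as root
    attributes so a run can be reconstructed from its output alone.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("series")
        g.create_dataset("iterations", data=traj.iterations)
        g.create_dataset("ubar", data=traj.ubar)
        g.create_dataset("sigma", data=traj.sigma)
        g.create_dataset("cov", data=traj.cov)
        if traj.u_snapshots is not None:
            s = f.create_group("snapshots")
            s.create_dataset("iterations", data=traj.snapshot_iterations)
            s.create_dataset("u", data=traj.u_snapshots, compression="gzip")
            s.create_dataset("v", data=traj.v_snapshots, compression="gzip")
        if traj.lattice is not None:
            lat = f.create_group("lattice")
            lat.create_dataset("type_map", data=traj.lattice.type_map)
            lat.attrs.update(
                N=traj.lattice.size,
                phi1=traj.lattice.phi1,
                phi2=traj.lattice.phi2,
                seed=traj.lattice.seed,
            )
        if traj.params is not None:
            f.attrs["params_json"] = json.dumps(traj.params.to_dict())
        if traj.seed is not None:
            f.attrs["seed"] = traj.seed
        f.attrs["meta_json"] = json.dumps(traj.meta)


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        g = f["series"]
        kwargs = dict(
            iterations=g["iterations"][:],
            ubar=g["ubar"][:],
            sigma=g["sigma"][:],
            cov=g["cov"][:],
            snapshot_iterations=np.asarray([], dtype=int),
        )
        if "snapshots" in f:
            s = f["snapshots"]
            kwargs.update(
                snapshot_iterations=s["iterations"][:],
                u_snapshots=s["u"][:],
                v_snapshots=s["v"][:],
            )
        if "lattice" in f:
            lat = f["lattice"]
            kwargs["lattice"] = PopulationLattice(
                size=int(lat.attrs["N"]),
                type_map=lat["type_map"][:],
                phi1=float(lat.attrs["phi1"]),
                phi2=float(lat.attrs["phi2"]),
                seed=int(lat.attrs["seed"]),
            )
        if "params_json" in f.attrs:
            kwargs["params"] = ModelParams(**json.loads(f.attrs["params_json"]))
        if "seed" in f.attrs:
            kwargs["seed"] = int(f.attrs["seed"])
        if "meta_json" in f.attrs:
            kwargs["meta"] = json.loads(f.attrs["meta_json"])
    return Trajectory(**kwargs)


def series_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy per-iteration summary table (iteration, ubar, sigma, cov)."""
    return pd.DataFrame(
        {
            "iteration": traj.iterations,
            "ubar": traj.ubar,
            "sigma": traj.sigma,
            "cov": traj.cov,
        }
    )


def save_series_csv(traj: Trajectory, path: str | Path) -> None:
    series_frame(traj).to_csv(path, index=False)
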