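"""HDF5 containers for solver runs, datasets, and impedance kernels."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .impedance import ImpedanceKernel
from .experiments import SimDataset
from .network import ParameterSpace

__all__ = [
    "save_sim_result",
    "save_dataset",
    "load_dataset",
    "save_kernels",
    "load_kernels",
]


def save_sim_result(result, path, provenance: dict | None = None):
    """Per-vessel groups with x, t, q, p, A datasets plus provenance attrs."""
    with h5py.File(path, "w") as fh:
        fh.attrs["converged"] = result.converged
        fh.attrs["n_cycles"] = result.n_cycles
        if provenance:
            fh.attrs["provenance"] = json.dumps(provenance)
        for vid, fld in result.fields.items():
            g = fh.create_group(f"vessel_{vid}")
            g.create_dataset("x", data=fld.x_grid)
            g.create_dataset("t", data=fld.t_grid)
            g.create_dataset("q", data=fld.q)
            g.create_dataset("p", data=fld.p)
            g.create_dataset("A", data=fld.A)


def save_dataset(ds: SimDataset, path, provenance: dict | None = None):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("thetas", data=ds.thetas)
        fh.create_dataset("times", data=ds.times)
        fh.attrs["names"] = json.dumps(list(ds.space.names))
        fh.attrs["lower"] = ds.space.lower
        fh.attrs["upper"] = ds.space.upper
        fh.attrs["failed"] = np.asarray(ds.failed, dtype=np.int64)
        if provenance:
            fh.attrs["provenance"] = json.dumps(provenance)
        for vid in ds.q:
            g = fh.create_group(f"vessel_{vid}")
            g.create_dataset("q", data=ds.q[vid])
            g.create_dataset("p", data=ds.p[vid])


def load_dataset(path) -> SimDataset:
    with h5py.File(path, "r") as fh:
        space = ParameterSpace(
            tuple(json.loads(fh.attrs["names"])),
            np.asarray(fh.attrs["lower"]),
            np.asarray(fh.attrs["upper"]),
        )
        q, p = {}, {}
        for key in fh:
            if key.startswith("vessel_"):
                vid = int(key.split("_")[1])
                q[vid] = fh[key]["q"][...]
                p[vid] = fh[key]["p"][...]
        return SimDataset(
            thetas=fh["thetas"][...],
            times=fh["times"][...],
            q=q,
            p=p,
            space=space,
            failed=list(fh.attrs.get("failed", [])),
        )


def save_kernels(kernels: dict[int, ImpedanceKernel], path):
    """Kernel cache: group per terminal vessel with Z and z_time datasets."""
    with h5py.File(path, "w") as fh:
        for vid, k in kernels.items():
            g = fh.create_group(f"vessel_{vid}")
            g.create_dataset("Z_real", data=k.Z_root.real)
            g.create_dataset("Z_imag", data=k.Z_root.imag)
            g.create_dataset("z_time", data=k.z_time)
            g.attrs["period_T"] = k.period_T
            g.attrs["m"] = k.m
            g.attrs["root_radius"] = k.root_radius


def load_kernels(path) -> dict[int, ImpedanceKernel]:
    out = {}
    with h5py.File(path, "r") as fh:
        for key in fh:
            vid = int(key.split("_")[1])
            g = fh[key]
            Z = g["Z_real"][...] + 1j * g["Z_imag"][...]
            m = int(g.attrs["m"])
            T = float(g.attrs["period_T"])
            out[vid] = ImpedanceKernel(
                frequencies=2.0 * np.pi * np.arange(m) / T,
                Z_root=Z,
                z_time=g["z_time"][...],
                period_T=T,
                m=m,
                root_radius=float(g.attrs["root_radius"]),
            )
    return out
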