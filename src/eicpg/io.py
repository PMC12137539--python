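"""HDF5 / YAML persistence for networks, trajectories, and configs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .network import Connectivity, SimulationResult
from .params import NetworkParams

__all__ = ["save_connectivity", "load_connectivity", "save_run",
           "params_from_yaml", "params_to_yaml"]


def save_connectivity(conn: Connectivity, path: str | Path) -> None:
    """Write one network instance to HDF5; the sparse recurrent matrix is
    stored as (row, col, value) triplets, parameters as root attributes."""
    with h5py.File(path, "w") as f:
        r, c = np.nonzero(conn.j_rec)
        f.create_dataset("j_rec_row", data=r.astype(np.int32))
        f.create_dataset("j_rec_col", data=c.astype(np.int32))
        f.create_dataset("j_rec_val", data=conn.j_rec[r, c])
        f.create_dataset("j_in", data=conn.j_in)
        f.create_dataset("j_fb", data=conn.j_fb)
        f.create_dataset("w_out", data=conn.w_out)
        for key, val in asdict(conn.params).items():
            f.attrs[key] = val


def load_connectivity(path: str | Path) -> Connectivity:
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        params = NetworkParams(**{k: (v.item() if hasattr(v, "item") else v)
                                  for k, v in attrs.items()})
        ntot = params.n_exc + params.n_inh
        j_rec = np.zeros((ntot, ntot))
        j_rec[f["j_rec_row"][:], f["j_rec_col"][:]] = f["j_rec_val"][:]
        return Connectivity(j_rec=j_rec, j_in=f["j_in"][:], j_fb=f["j_fb"][:],
                            w_out=f["w_out"][:], params=params)


def save_run(sim: SimulationResult, path: str | Path,
             include_activations: bool = False) -> None:
    """Persist trajectories of one simulation run."""
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=sim.rates, compression="gzip")
        f.create_dataset("outputs", data=sim.outputs, compression="gzip")
        if include_activations and sim.activations.size:
            f.create_dataset("activations", data=sim.activations,
                             compression="gzip")


def params_from_yaml(path: str | Path) -> NetworkParams:
    """Read a NetworkParams block from a YAML (or JSON) config file."""
    return NetworkParams(**(yaml.safe_load(Path(path).read_text()) or {}))


def params_to_yaml(params: NetworkParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(params)))
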