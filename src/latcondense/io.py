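"""File output: CSV summary tables and HDF5 field snapshots.

Every artifact embeds the full parameter set, code version and seed so that
a run is reproducible from the file alone.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__


def _param_items(params) -> dict:
    if params is None:
        return {}
    if dataclasses.is_dataclass(params):
        return dataclasses.asdict(params)
    if isinstance(params, dict):
        return params
    return {"params": repr(params)}


def write_summary(table: pd.DataFrame, path, params=None, seed=None) -> None:
    """Write a CSV with a '#'-prefixed header block echoing the run metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# latcondense {__version__}\n")
    if seed is not None:
        buf.write(f"# seed: {seed}\n")
    for k, v in _param_items(params).items():
        buf.write(f"# {k}: {v}\n")
    table.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_summary(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_summary` (comment lines skipped)."""
    return pd.read_csv(path, comment="#")


def save_snapshots_h5(path, snapshots, params=None, grid=None, seed=None) -> None:
    """Store field snapshots: groups snap_000…/datasets L, B; params as attrs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        if seed is not None:
            f.attrs["seed"] = seed
        for k, v in _param_items(params).items():
            f.attrs[k] = v if isinstance(v, (int, float, str, bool)) else repr(v)
        if grid is not None:
            f.attrs["grid_n"] = grid.n
            f.attrs["grid_box"] = grid.box
        for i, s in enumerate(snapshots):
            grp = f.create_group(f"snap_{i:04d}")
            grp.attrs["t_star"] = s.t_star
            grp.create_dataset("L", data=s.L, compression="gzip")
            grp.create_dataset("B", data=s.B, compression="gzip")


def load_snapshots_h5(path):
    """Load snapshots back as FieldState objects plus the root attributes."""
    from .field_dynamics import FieldState

    snaps, attrs = [], {}
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        for name in sorted(k for k in f.keys() if k.startswith("snap_")):
            grp = f[name]
            snaps.append(
                FieldState(
                    L=np.asarray(grp["L"]),
                    B=np.asarray(grp["B"]),
                    t_star=float(grp.attrs["t_star"]),
                )
            )
    return snaps, attrs


def trajectory_table(traj) -> pd.DataFrame:
    """Aggregation trajectory as a (t_star, mean_size, mass_retained) table."""
    return pd.DataFrame(
        {
            "t_star": traj.times,
            "mean_size": traj.mean_sizes,
            "mass_retained": traj.mass_retained,
        }
    )


def save_distribution_h5(path, traj, params=None) -> None:
    """Full cluster-size distribution matrix (time x size) with parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    c = np.vstack([s.c for s in traj.states])
    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        for k, v in _param_items(params).items():
            f.attrs[k] = v
        f.create_dataset("c", data=c, compression="gzip")
        f.create_dataset("t_star", data=traj.times)
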