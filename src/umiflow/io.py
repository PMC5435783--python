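"""File formats: HDF5 for grids/frames/fields, CSV for signals and series,
TIFF for image stacks.

HDF5 schemas
------------
Grid (group or file root): datasets ``wall_lower_y``, ``wall_upper_y``;
attrs ``nx``, ``ny``, ``dx``, ``dy``.

Doppler frame stack: ``/beam`` (2,), one group ``/frames/<k>`` per frame
with datasets ``vm``, ``valid`` and attr ``t``.

Flow-field stack: one group ``/frames/<k>`` per time level with datasets
``u``, ``v``, ``p`` and attr ``t``; root attr ``dt``.

Signal CSV: two columns ``t,value`` with ``# fs=..., t0=..., kind=...``
header comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from umiflow.assimilation import DopplerFrame, ErrorNormSeries, SimulationResult
from umiflow.biosignals import BioSignal
from umiflow.geometry import Grid2D
from umiflow.solver import FlowField


# ---------------------------------------------------------------------------
# grids


def save_grid(path, grid: Grid2D) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["nx"] = grid.nx
        f.attrs["ny"] = grid.ny
        f.attrs["dx"] = grid.dx
        f.attrs["dy"] = grid.dy
        f.create_dataset("wall_lower_y", data=grid.wall_lower_y)
        f.create_dataset("wall_upper_y", data=grid.wall_upper_y)


def load_grid(path) -> Grid2D:
    with h5py.File(path, "r") as f:
        return Grid2D(
            nx=int(f.attrs["nx"]),
            ny=int(f.attrs["ny"]),
            dx=float(f.attrs["dx"]),
            dy=float(f.attrs["dy"]),
            wall_lower_y=f["wall_lower_y"][:],
            wall_upper_y=f["wall_upper_y"][:],
        )


# ---------------------------------------------------------------------------
# Doppler frames


def save_frames(path, frames: list) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("beam", data=frames[0].beam)
        grp = f.create_group("frames")
        for k, fr in enumerate(frames):
            g = grp.create_group(str(k))
            g.create_dataset("vm", data=fr.vm)
            g.create_dataset("valid", data=fr.valid)
            g.attrs["t"] = fr.t


def load_frames(path) -> list:
    with h5py.File(path, "r") as f:
        beam = f["beam"][:]
        keys = sorted(f["frames"].keys(), key=int)
        return [
            DopplerFrame(
                vm=f["frames"][k]["vm"][:],
                beam=beam,
                t=float(f["frames"][k].attrs["t"]),
                valid=f["frames"][k]["valid"][:].astype(bool),
            )
            for k in keys
        ]


# ---------------------------------------------------------------------------
# flow fields


def save_fields(path, fields: list, dt: float) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = dt
        grp = f.create_group("frames")
        for k, fld in enumerate(fields):
            g = grp.create_group(str(k))
            g.create_dataset("u", data=fld.u)
            g.create_dataset("v", data=fld.v)
            g.create_dataset("p", data=fld.p)
            g.attrs["t"] = fld.t


def load_fields(path) -> list:
    with h5py.File(path, "r") as f:
        keys = sorted(f["frames"].keys(), key=int)
        return [
            FlowField(
                u=f["frames"][k]["u"][:],
                v=f["frames"][k]["v"][:],
                p=f["frames"][k]["p"][:],
                t=float(f["frames"][k].attrs["t"]),
            )
            for k in keys
        ]


# ---------------------------------------------------------------------------
# signals and series


def save_signal(path, sig: BioSignal) -> None:
    with open(path, "w") as f:
        f.write(f"# fs={sig.fs!r}, t0={sig.t0!r}, kind={sig.kind}\n")
        pd.DataFrame({"t": sig.t, "value": sig.samples}).to_csv(f, index=False)


def load_signal(path) -> BioSignal:
    with open(path) as f:
        header = f.readline().strip()
    meta = dict(
        item.strip().split("=") for item in header.lstrip("# ").split(",")
    )
    df = pd.read_csv(path, comment="#")
    return BioSignal(
        df["value"].to_numpy(), fs=float(meta["fs"]), t0=float(meta["t0"]),
        kind=meta["kind"],
    )


def save_error_series(path, result: SimulationResult) -> None:
    pd.DataFrame(
        {
            "t": result.error_norm.t,
            "e": result.error_norm.e,
            "U_in": result.inlet_velocity,
        }
    ).to_csv(path, index=False)


def save_wss_series(path, times: np.ndarray, wss: np.ndarray) -> None:
    """Per-frame per-column WSS as tidy CSV (t, x_index, tau)."""
    n_t, n_x = wss.shape
    pd.DataFrame(
        {
            "t": np.repeat(times, n_x),
            "x": np.tile(np.arange(n_x), n_t),
            "tau": wss.ravel(),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image stacks and summaries


def save_bmode(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, (np.clip(stack, 0, 1.3) / 1.3 * 65535).astype(np.uint16))


def load_bmode(path) -> np.ndarray:
    return tifffile.imread(path).astype(float) / 65535.0 * 1.3


def save_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
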