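"""File formats: text-grid field directories, HDF5 containers, annotated CSV.

Two interchangeable representations of a velocity-field series:

* a directory of per-frame whitespace-delimited text grids
  (``vx_0000.txt``, ``vy_0000.txt``, ...) plus a ``meta.yaml`` sidecar with
  the grid spacing (um), frame times (s) and origin — convenient for
  inspection and for ingesting third-party PIV exports;
* a single HDF5 container with datasets ``/times``, ``/vx``, ``/vy`` and
  the grid metadata as attributes — convenient for round-tripping.

Tabular outputs are CSV with unit-annotated column headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .fields import VectorFieldSeries

__all__ = [
    "save_field_text",
    "load_field_text",
    "save_field_h5",
    "load_field_h5",
    "save_table",
]


def save_field_text(fld: VectorFieldSeries, directory: str | Path) -> Path:
    """Write one text grid per frame per component plus a ``meta.yaml`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(fld.n_frames):
        np.savetxt(directory / f"vx_{k:04d}.txt", fld.vx[k])
        np.savetxt(directory / f"vy_{k:04d}.txt", fld.vy[k])
    meta = {
        "spacing_um": float(fld.spacing),
        "origin_um": [float(fld.origin[0]), float(fld.origin[1])],
        "times_s": [float(t) for t in fld.times],
        "units": "um/s",
    }
    (directory / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return directory


def load_field_text(directory: str | Path) -> VectorFieldSeries:
    """Read a field directory written by :func:`save_field_text`.

    Missing vectors may be encoded as ``nan``; they are flagged and
    infilled on ingestion.
    """
    directory = Path(directory)
    meta = yaml.safe_load((directory / "meta.yaml").read_text())
    times = np.asarray(meta["times_s"], dtype=float)
    vx = np.stack(
        [np.loadtxt(directory / f"vx_{k:04d}.txt") for k in range(times.size)]
    )
    vy = np.stack(
        [np.loadtxt(directory / f"vy_{k:04d}.txt") for k in range(times.size)]
    )
    return VectorFieldSeries.from_raw(
        times, vx, vy, float(meta["spacing_um"]), tuple(meta["origin_um"])
    )


def save_field_h5(fld: VectorFieldSeries, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=fld.times)
        h5.create_dataset("vx", data=fld.vx)
        h5.create_dataset("vy", data=fld.vy)
        h5.attrs["spacing_um"] = fld.spacing
        h5.attrs["origin_um"] = list(fld.origin)
        if fld.gap_fraction is not None:
            h5.create_dataset("gap_fraction", data=fld.gap_fraction)
    return path


def load_field_h5(path: str | Path) -> VectorFieldSeries:
    with h5py.File(path, "r") as h5:
        fld = VectorFieldSeries(
            h5["times"][:],
            h5["vx"][:],
            h5["vy"][:],
            float(h5.attrs["spacing_um"]),
            tuple(h5.attrs["origin_um"]),
            h5["gap_fraction"][:] if "gap_fraction" in h5 else None,
        )
    return fld


def save_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """CSV writer; column names are expected to carry units (``_um``, ``_per_s``).

    Optional metadata (seeds, config hashes) goes to a ``.json`` sidecar
    rather than into CSV comments, keeping the CSV trivially parseable.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if meta:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path
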