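"""Time-series field I/O: CSV-per-timestep with a JSON manifest, or HDF5."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .indices import VolumeSeries, WallSeries

__all__ = ["write_series_csv", "read_series_csv", "write_series_h5", "read_series_h5"]

_VEC_COLS = ["vx", "vy", "vz"]


def write_series_csv(series, directory: str, prefix: str = "step") -> str:
    """Write one CSV per timestep plus ``manifest.json``; returns manifest path."""
    os.makedirs(directory, exist_ok=True)
    files = []
    for i, t in enumerate(series.times):
        name = f"{prefix}_{i:04d}.csv"
        df = pd.DataFrame(
            np.hstack([series.points, series.vectors[i]]),
            columns=["x", "y", "z", *_VEC_COLS],
        )
        if series.weights is not None:
            df["w"] = series.weights
        df.to_csv(os.path.join(directory, name), index=False)
        files.append({"time": float(t), "file": name})
    manifest = {
        "period": float(series.period),
        "kind": "wall" if isinstance(series, WallSeries) else "volume",
        "steps": files,
    }
    if isinstance(series, VolumeSeries):
        manifest["rho"] = float(series.rho)
    path = os.path.join(directory, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def read_series_csv(manifest_path: str):
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = os.path.dirname(manifest_path)
    times, vectors, points, weights = [], [], None, None
    for step in manifest["steps"]:
        df = pd.read_csv(os.path.join(base, step["file"]))
        if points is None:
            points = df[["x", "y", "z"]].to_numpy()
            weights = df["w"].to_numpy() if "w" in df else None
        times.append(step["time"])
        vectors.append(df[_VEC_COLS].to_numpy())
    kw = dict(
        points=points,
        vectors=np.array(vectors),
        times=np.array(times),
        period=manifest["period"],
        weights=weights,
    )
    if manifest["kind"] == "wall":
        return WallSeries(**kw)
    return VolumeSeries(**kw, rho=manifest.get("rho", 1055.0))


def write_series_h5(series, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("points", data=series.points)
        fh.create_dataset("vectors", data=series.vectors)
        fh.create_dataset("times", data=series.times)
        if series.weights is not None:
            fh.create_dataset("weights", data=series.weights)
        fh.attrs["period"] = series.period
        fh.attrs["kind"] = "wall" if isinstance(series, WallSeries) else "volume"
        if isinstance(series, VolumeSeries):
            fh.attrs["rho"] = series.rho


def read_series_h5(path: str):
    import h5py

    with h5py.File(path, "r") as fh:
        kw = dict(
            points=fh["points"][()],
            vectors=fh["vectors"][()],
            times=fh["times"][()],
            period=float(fh.attrs["period"]),
            weights=fh["weights"][()] if "weights" in fh else None,
        )
        kind = fh.attrs["kind"]
        rho = float(fh.attrs.get("rho", 1055.0))
    if kind == "wall":
        return WallSeries(**kw)
    return VolumeSeries(**kw, rho=rho)
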