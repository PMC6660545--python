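"""Reading and writing traces, jump pools, and fit results.

Traces travel as single-column CSV (header ``value``) with a JSON sidecar
holding the sampling interval, model parameters, seed, and -- for simulated
fixtures -- the ground-truth jump log.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GriddedDensity, GriddedFunction
from .simulator import (
    JumpDiffusionModel,
    LognormalJumps,
    SimulatedSeries,
    UniformTimeSeries,
)


def save_series(
    prefix: str | Path,
    series: UniformTimeSeries,
    model: JumpDiffusionModel | None = None,
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (column ``value``) and ``<prefix>.json``."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame({"value": series.values}).to_csv(csv_path, index=False)
    meta: dict = {"dt": series.dt, "n": int(series.n), "seed": seed}
    if model is not None:
        meta["model"] = describe_model(model)
    if isinstance(series, SimulatedSeries):
        meta["true_jump_times"] = series.jump_times.tolist()
        meta["true_jump_amplitudes"] = series.jump_amplitudes.tolist()
    json_path.write_text(json.dumps(meta))
    return csv_path, json_path


def load_series(path: str | Path, dt: float | None = None) -> UniformTimeSeries:
    """Read a trace from CSV (column ``value`` or single-column) with dt from
    the argument or from a ``.json`` sidecar next to the file."""
    path = Path(path)
    df = pd.read_csv(path)
    col = "value" if "value" in df.columns else df.columns[0]
    values = df[col].to_numpy(dtype=float)
    if dt is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError("dt not given and no JSON sidecar found")
        dt = float(json.loads(sidecar.read_text())["dt"])
    return UniformTimeSeries(values=values, dt=dt)


def describe_model(model: JumpDiffusionModel) -> dict:
    desc: dict = {
        "noise_intensity": model.noise_intensity,
        "jump_rate": model.jump_rate,
        "dt": model.dt,
    }
    if isinstance(model.jump_dist, LognormalJumps):
        desc["jump_dist"] = {
            "family": "lognormal",
            "mu": model.jump_dist.mu,
            "sigma": model.jump_dist.sigma,
        }
    elif isinstance(model.jump_dist, GriddedDensity):
        desc["jump_dist"] = {"family": "gridded"}
    else:
        desc["jump_dist"] = None
    desc["drift"] = "gridded" if isinstance(model.drift, GriddedFunction) else "callable"
    return desc


def save_gridded(path: str | Path, g: GriddedFunction, value_name: str = "value") -> Path:
    path = Path(path)
    pd.DataFrame({"grid": g.x, value_name: g.y}).to_csv(path, index=False)
    return path
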