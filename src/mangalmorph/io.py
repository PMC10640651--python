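"""Persistence: gridded snapshots, metric tables and checkpoints.

Snapshots are self-describing xarray datasets (netCDF, scipy backend) with
coordinates in metres, units on every variable, and the configuration hash
in the global attributes so a resumed run can refuse mismatched state.
Metric tables are tidy long-format CSV (one row per year/scenario/metric).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import RunConfig
from .engine import RunState
from .scenarios import ScenarioPlan

_SNAPSHOT_UNITS = {
    "elevation": "m MSL",
    "mud_fraction_top1m": "1",
    "stems": "1",
    "stem_diameter_cm": "cm",
    "hydroperiod": "1",
    "tau_max": "N m-2",
}


def write_snapshot(state: RunState, epoch: float, path, config: RunConfig,
                   plan: ScenarioPlan) -> Path:
    """Write the gridded fields stored for one output epoch.

    The epoch must be one of the plan's output epochs and present in the
    state; writes are bit-stable for a given (config, seed) run.
    """
    if not any(abs(epoch - e) < 1e-9 for e in plan.output_epochs):
        raise ValueError(f"epoch {epoch} is not an output epoch of the plan")
    if epoch not in state.snapshots:
        raise ValueError(f"no snapshot stored for year {epoch}")
    fields = state.snapshots[epoch]
    ny, nx = fields["elevation"].shape
    dx = config.grid.resolution
    coords = {
        "y": ("y", np.arange(ny) * dx, {"units": "m"}),
        "x": ("x", np.arange(nx) * dx,
              {"units": "m", "long_name": "seaward -> landward"}),
    }
    data = {}
    for name, arr in fields.items():
        attrs = {"units": _SNAPSHOT_UNITS.get(name, "1")}
        data[name] = (("y", "x"), np.asarray(arr), attrs)
    ds = xr.Dataset(data, coords=coords, attrs={
        "config_hash": config.config_hash(),
        "scenario": plan.name,
        "year": float(epoch),
        "convention": "cell-centred scalar fields, 0-based indices",
    })
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_snapshot(path, config: RunConfig | None = None) -> xr.Dataset:
    """Read a snapshot; verify the configuration hash when one is given."""
    ds = xr.open_dataset(path, engine="scipy").load()
    if config is not None and ds.attrs.get("config_hash") != config.config_hash():
        raise ValueError("snapshot was produced under a different configuration")
    return ds


def export_metrics(frame: pd.DataFrame, path) -> Path:
    """Write the annual metrics as a tidy long table.

    Schema: ``year, scenario, metric, value`` — one row per combination;
    re-export of the same frame is byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if frame.empty:
        pd.DataFrame(columns=["year", "scenario", "metric", "value"]).to_csv(
            path, index=False)
        return path
    long = frame.melt(id_vars=["year", "scenario"], var_name="metric",
                      value_name="value")
    long = long.sort_values(["year", "scenario", "metric"], kind="mergesort")
    long.to_csv(path, index=False, float_format="%.10g")
    return path


def save_checkpoint(state: RunState, path, config: RunConfig) -> Path:
    """Serialize a run state so management branches can resume from it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        config_hash=np.array(config.config_hash()),
        year=state.year, season=state.season, t=state.t, parity=state.parity,
        eta=state.flow.eta, u=state.flow.u, v=state.flow.v,
        z=state.bed.z, th=state.bed.th, fr=state.bed.fr, nlay=state.bed.nlay,
        non_erodible=state.bed.non_erodible, z_floor=state.bed.z_floor,
        stems=state.veg.stems, d_cm=state.veg.d_cm, age=state.veg.age,
        supp=state.veg.supp, pneu_m=state.veg.pneu_m,
        pneu_timer=state.veg.pneu_timer,
        colonize_block=state.veg.colonize_block,
        m_mud=state.m_mud, m_sand=state.m_sand,
        hp=state.hp, tau_max=state.tau_max, tau_mean=state.tau_mean,
        tp=state.tp,
    )
    return path


def load_checkpoint(path, config: RunConfig):
    """Restore a run state; refuses checkpoints from another configuration."""
    from .hydro import FlowState
    from .sediment import BedState
    from .vegetation import VegetationState

    d = np.load(Path(path))
    if str(d["config_hash"]) != config.config_hash():
        raise ValueError("checkpoint was produced under a different configuration")
    state = RunState(
        year=float(d["year"]), season=int(d["season"]), t=float(d["t"]),
        parity=int(d["parity"]),
        flow=FlowState(d["eta"], d["u"], d["v"]),
        bed=BedState(d["z"], d["th"], d["fr"], d["nlay"],
                     d["non_erodible"], d["z_floor"]),
        veg=VegetationState(d["stems"], d["d_cm"], d["age"], d["supp"],
                            d["pneu_m"], d["pneu_timer"],
                            d["colonize_block"]),
        m_mud=d["m_mud"], m_sand=d["m_sand"],
        hp=d["hp"], tau_max=d["tau_max"], tau_mean=d["tau_mean"],
        tp=float(d["tp"]),
    )
    return state
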