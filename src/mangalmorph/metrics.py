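"""Estuarine landscape diagnostics.

All reported quantities: accommodation space (basin volume below high
tide), the muddy region (area whose top metre of substrate exceeds 30 % mud
content), mangrove coverage, the relative basin area above mean sea level
(A_MSL/A_tot, the potential mangrove habitat), catchment sediment yield
against tidal prism (SY/TP), channel classification by residual relief, and
distance-binned sedimentation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SedimentConfig


def accommodation_space(z, basin_mask, high_water, cell_area) -> float:
    """Basin volume (m3) below the high-tide level that sediment can fill."""
    z = np.asarray(z, dtype=float)
    return float(np.maximum(high_water - z[basin_mask], 0.0).sum() * cell_area)


def muddy_region_fraction(top1m_mud_fraction, basin_mask,
                          threshold=0.30) -> float:
    """Fraction of the basin whose top-1 m mud fraction strictly exceeds the
    threshold (30 %)."""
    f = np.asarray(top1m_mud_fraction, dtype=float)
    n = int(basin_mask.sum())
    return float((f[basin_mask] > threshold).sum()) / n if n else 0.0


def mangrove_coverage(veg_mask, basin_mask) -> float:
    """Vegetated fraction of the basin area."""
    n = int(basin_mask.sum())
    return float((veg_mask & basin_mask).sum()) / n if n else 0.0


def relative_area_amsl(z, basin_mask, high_water) -> float:
    """A_MSL/A_tot: basin cells above mean sea level (and still below high
    water) over basin cells wetted at high tide."""
    z = np.asarray(z, dtype=float)
    zb = z[basin_mask]
    den = int((zb < high_water).sum())
    num = int(((zb > 0.0) & (zb < high_water)).sum())
    return num / den if den else 0.0


@dataclass
class ChannelClassification:
    """Channel mask, Euclidean distance to it, and the distance classes used
    for the sedimentation-pattern comparison."""

    channel: np.ndarray        # bool, channelized cells
    distance: np.ndarray       # m, 0 on channel cells
    near: np.ndarray           # unchannelized, < 100 m from a channel
    far: np.ndarray            # unchannelized, 300-400 m from a channel


def classify_channels(z, basin_mask, dx, window_m=540.0, relief_threshold=0.3,
                      mean_low_water=-0.75) -> ChannelClassification:
    """Identify channels from residual relief.

    A basin cell is channelized when it sits more than ``relief_threshold``
    below the moving-window median bed level, or is subtidal (below mean low
    water) while still lying below the local median — so an early-stage,
    uniformly subtidal basin is not classified wall-to-wall as channel.
    Distances are Euclidean to the nearest channel cell.
    """
    z = np.asarray(z, dtype=float)
    win = max(3, int(round(window_m / dx)) | 1)  # odd window
    med = ndimage.median_filter(z, size=win, mode="nearest")
    subtidal = (z < mean_low_water) & (z < med - 0.5 * relief_threshold)
    channel = basin_mask & ((z < med - relief_threshold) | subtidal)
    if channel.any():
        distance = ndimage.distance_transform_edt(~channel) * dx
    else:
        distance = np.full(z.shape, np.inf)
    near = basin_mask & ~channel & (distance > 0) & (distance < 100.0)
    far = basin_mask & ~channel & (distance >= 300.0) & (distance <= 400.0)
    return ChannelClassification(channel=channel, distance=distance,
                                 near=near, far=far)


def sedimentation_rate(z_start, z_end, years):
    """Bed-level change rate (mm/yr) between two snapshots."""
    if years <= 0:
        raise ValueError("snapshots must be at least a year apart")
    return (np.asarray(z_end, dtype=float) - np.asarray(z_start, dtype=float)) \
        / years * 1000.0


def rate_by_class(rates, classification: ChannelClassification) -> dict:
    """Mean sedimentation rate (mm/yr) per spatial class."""
    out = {}
    for name, mask in (("channel", classification.channel),
                       ("near", classification.near),
                       ("far", classification.far)):
        out[name] = float(np.mean(rates[mask])) if mask.any() else np.nan
    return out


def sediment_yield_and_prism(sy_mass_kg_yr, tidal_prism_m3,
                             cfg: SedimentConfig | None = None) -> dict:
    """Non-dimensional catchment sediment yield.

    SY is converted from annual mass to volume through the dry mud density
    so SY/TP is a volume-per-volume ratio (annual yield over the volume
    exchanged through the inlet in one tidal cycle).
    """
    p = cfg or SedimentConfig()
    sy_vol = sy_mass_kg_yr / p.rho_dry_mud
    ratio = sy_vol / tidal_prism_m3 if tidal_prism_m3 > 0 else np.nan
    return {"SY_kg_yr": float(sy_mass_kg_yr), "SY_m3_yr": float(sy_vol),
            "TP_m3": float(tidal_prism_m3), "SY_TP": float(ratio)}


def read_estuary_table(path) -> pd.DataFrame:
    """Read a small table of real-estuary trajectory points.

    Expected columns: ``estuary``, ``SY_m3_yr``, ``TP_m3``, ``A_MSL_A_tot``;
    used to overlay observed systems on the simulated landscape-trajectory
    diagram.
    """
    df = pd.read_csv(path)
    required = {"estuary", "SY_m3_yr", "TP_m3", "A_MSL_A_tot"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"estuary table missing columns: {sorted(missing)}")
    df["SY_TP"] = df["SY_m3_yr"] / df["TP_m3"]
    return df
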