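"""Sand and mud morphodynamics with substrate stratigraphy.

Mud exchange follows the Partheniades-Krone threshold law; sand uses a
reduced-complexity capacity formulation (equilibrium suspended concentration
plus a slope-corrected bed-load vector) rather than a full Van Rijn
predictor — sand dynamics mainly shape the spin-up morphology while the
management findings concern mud.  The bed keeps a per-cell layer stack
(thickness + mud fraction) so that the "muddy region" metric can interrogate
the top metre of substrate, and all bed changes are accelerated by the
morphological factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .config import GridConfig, SedimentConfig
from .domain import GridSpec, initial_elevation


@dataclass
class BedState:
    """Bed elevation plus vertical stratigraphy (substrate memory)."""

    z: np.ndarray              # (ny, nx) elevation (m MSL)
    th: np.ndarray             # (ny, nx, L) layer thickness (m), bottom-up
    fr: np.ndarray             # (ny, nx, L) layer mud volume fraction [0, 1]
    nlay: np.ndarray           # (ny, nx) int32 active layer count
    non_erodible: np.ndarray   # (ny, nx) bool
    z_floor: np.ndarray        # (ny, nx) base of the tracked substrate

    def copy(self) -> "BedState":
        return BedState(self.z.copy(), self.th.copy(), self.fr.copy(),
                        self.nlay.copy(), self.non_erodible.copy(),
                        self.z_floor.copy())

    def summaries(self, active_layer: float):
        """Active-layer mud fraction, available mud/sand volume (m) and the
        top-1 m mud fraction, all per cell."""
        ny, nx = self.z.shape
        frac_mud = np.zeros((ny, nx))
        avail_mud = np.zeros((ny, nx))
        avail_sand = np.zeros((ny, nx))
        top1m = np.zeros((ny, nx))
        K.stack_summaries(self.th, self.fr, self.nlay, active_layer,
                          frac_mud, avail_mud, avail_sand, top1m)
        return frac_mud, avail_mud, avail_sand, top1m

    def species_volumes(self):
        """Total mud and sand volume per cell (m) in the stack."""
        mud = (self.th * self.fr).sum(axis=2)
        sand = (self.th * (1.0 - self.fr)).sum(axis=2)
        return mud, sand

    def apply_season(self, dvol_mud, dvol_sand, cfg: SedimentConfig) -> float:
        """Apply net per-cell species volume changes (m) and refresh z.

        Returns the erosion shortfall (m of volume requested but absent from
        the stack; stays 0 when availability capping is active upstream).
        """
        short = K.apply_season_to_stack(self.th, self.fr, self.nlay,
                                        np.ascontiguousarray(dvol_mud),
                                        np.ascontiguousarray(dvol_sand),
                                        cfg.layer_thickness, cfg.max_layers)
        erod = ~self.non_erodible
        self.z[erod] = self.z_floor[erod] + self.th.sum(axis=2)[erod]
        return float(short)


def init_bathymetry(grid: GridSpec, grid_cfg: GridConfig | None = None,
                    sed_cfg: SedimentConfig | None = None) -> BedState:
    """Initial bed: basin at -1.5 m MSL, offshore sloping to -100 m, barrier
    cells non-erodible, substrate 100 % sand."""
    gcfg = grid_cfg or GridConfig()
    scfg = sed_cfg or SedimentConfig()
    z = initial_elevation(grid, gcfg)
    ny, nx = z.shape
    L = scfg.max_layers
    th = np.zeros((ny, nx, L))
    fr = np.zeros((ny, nx, L))
    nlay = np.zeros((ny, nx), dtype=np.int32)
    non_erod = grid.barrier_mask.copy()
    th[~non_erod, 0] = scfg.substrate_depth
    nlay[~non_erod] = 1
    z_floor = z - th.sum(axis=2)
    return BedState(z=z, th=th, fr=fr, nlay=nlay, non_erodible=non_erod,
                    z_floor=z_floor)


# ---------------------------------------------------------------------------
# pure flux operations (vectorized; the burst kernel applies the same laws)
# ---------------------------------------------------------------------------

def mud_exchange(tau, c_mud, params: SedimentConfig | None = None,
                 surface_mud_fraction=1.0):
    """Partheniades-Krone erosion and deposition fluxes (kg/m2/s).

    ``E = M max(tau/tau_ce - 1, 0)`` scaled by the mud availability of the
    surface layer; ``D = w_s c max(1 - tau/tau_cd, 0)``.
    """
    p = params or SedimentConfig()
    tau = np.asarray(tau, dtype=float)
    c = np.asarray(c_mud, dtype=float)
    ero = p.m_erosion * np.maximum(tau / p.tau_ce - 1.0, 0.0) * surface_mud_fraction
    dep = p.ws_mud * c * np.maximum(1.0 - tau / p.tau_cd, 0.0)
    return ero, dep


def sand_equilibrium_concentration(speed, params: SedimentConfig | None = None,
                                   depth=1.0):
    """Capacity concentration (kg/m3): zero below the critical mobility speed,
    increasing with the cube of excess mobility above it and decreasing with
    depth (so scouring channels converge on an equilibrium depth)."""
    p = params or SedimentConfig()
    sp2 = np.asarray(speed, dtype=float) ** 2
    ex = np.maximum(sp2 - p.sand_ucrit**2, 0.0)
    return p.sand_capacity_coeff * ex**1.5 / np.maximum(depth, 0.5)


def sand_transport(uc, vc, c_sand, params: SedimentConfig | None = None,
                   surface_sand_fraction=1.0, depth=1.0):
    """Suspended-sand source/sink and bed-load flux vector.

    Returns ``(net_source, (qbx, qby))`` where net_source (kg/m2/s) relaxes
    the suspended concentration toward capacity (positive = erosion) and the
    bed-load components (m2/s) are aligned with the flow.
    """
    p = params or SedimentConfig()
    uc = np.asarray(uc, dtype=float)
    vc = np.asarray(vc, dtype=float)
    sp = np.hypot(uc, vc)
    ceq = sand_equilibrium_concentration(sp, p, depth)
    src = p.ws_sand * (ceq * surface_sand_fraction - np.asarray(c_sand, dtype=float))
    ex = np.maximum(sp**2 - p.sand_ucrit**2, 0.0)
    mag = p.bedload_coeff * ex**1.5 * surface_sand_fraction
    with np.errstate(invalid="ignore", divide="ignore"):
        qbx = np.where(sp > 1e-8, mag * uc / sp, 0.0)
        qby = np.where(sp > 1e-8, mag * vc / sp, 0.0)
    return src, (qbx, qby)


def slope_correction(qbx, qby, z, dx, dy, params: SedimentConfig | None = None):
    """Koch-Flokstra-style bed-slope effect on bed-load.

    Adds a transverse component proportional to the cross-flow bed slope and
    damps (enhances) transport directed up (down) the longitudinal slope.
    Flat beds are returned unchanged; reversing the slope sign reverses the
    transverse component exactly.
    """
    p = params or SedimentConfig()
    qbx = np.asarray(qbx, dtype=float)
    qby = np.asarray(qby, dtype=float)
    z = np.asarray(z, dtype=float)
    dzdx = np.zeros_like(z)
    dzdy = np.zeros_like(z)
    dzdx[:, 1:-1] = (z[:, 2:] - z[:, :-2]) / (2.0 * dx)
    dzdy[1:-1, :] = (z[2:, :] - z[:-2, :]) / (2.0 * dy)
    mag = np.hypot(qbx, qby)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(mag > 0, qbx / mag, 0.0)
        ey = np.where(mag > 0, qby / mag, 0.0)
    s_long = ex * dzdx + ey * dzdy
    fac = np.clip(1.0 - p.slope_longitudinal * s_long, 0.0, 2.0)
    tx = dzdx - s_long * ex
    ty = dzdy - s_long * ey
    out_x = fac * mag * ex - p.slope_transverse * fac * mag * tx
    out_y = fac * mag * ey - p.slope_transverse * fac * mag * ty
    return out_x, out_y


def advect_diffuse(m, u, v, h, dt, dx, dy, sources=None, diffusivity=0.0,
                   tol=1e-10):
    """Conservative explicit upwind advection-diffusion of a depth-integrated
    tracer (kg/m2) under a frozen flow field; reference path used to verify
    the coupled transport kernel.

    ``u`` is (ny, nx+1) on x-faces, ``v`` (ny+1, nx) on y-faces, ``h`` the
    cell depth.  Raises when the advective CFL exceeds 1.
    """
    m = np.asarray(m, dtype=float).copy()
    h = np.asarray(h, dtype=float)
    ny, nx = m.shape
    # a cell can lose mass through all four faces at once
    courant = (2.0 * (np.max(np.abs(u)) / dx + np.max(np.abs(v)) / dy)
               + 4.0 * diffusivity / min(dx, dy) ** 2) * dt
    if courant > 1.0:
        raise ValueError("advective CFL exceeded")
    hu = np.zeros((ny, nx + 1))
    hu[:, 1:-1] = 0.5 * (h[:, :-1] + h[:, 1:])
    hv = np.zeros((ny + 1, nx))
    hv[1:-1, :] = 0.5 * (h[:-1, :] + h[1:, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(h > 1e-9, m / h, 0.0)
    fx = np.zeros((ny, nx + 1))
    fx[:, 1:-1] = np.where(u[:, 1:-1] > 0, c[:, :-1], c[:, 1:]) * u[:, 1:-1] * hu[:, 1:-1]
    fy = np.zeros((ny + 1, nx))
    fy[1:-1, :] = np.where(v[1:-1, :] > 0, c[:-1, :], c[1:, :]) * v[1:-1, :] * hv[1:-1, :]
    m += dt * ((fx[:, :-1] - fx[:, 1:]) / dx + (fy[:-1, :] - fy[1:, :]) / dy)
    if diffusivity > 0:
        g = np.zeros((ny, nx + 1))
        g[:, 1:-1] = diffusivity * hu[:, 1:-1] * (c[:, 1:] - c[:, :-1]) / dx
        m += dt * (g[:, 1:] - g[:, :-1]) / dx
        gy = np.zeros((ny + 1, nx))
        gy[1:-1, :] = diffusivity * hv[1:-1, :] * (c[1:, :] - c[:-1, :]) / dy
        m += dt * (gy[1:, :] - gy[:-1, :]) / dy
    if sources is not None:
        m += np.asarray(sources, dtype=float) * dt
    if m.min() < -tol:
        raise FloatingPointError("negative concentration beyond tolerance")
    np.clip(m, 0.0, None, out=m)
    return m


def update_bed(bed: BedState, dep_mud, ero_mud, dep_sand, ero_sand, morfac,
               dt, cfg: SedimentConfig | None = None) -> BedState:
    """Exner-style bed update from mass fluxes (kg/m2/s) over one interval.

    Deposition grows the top of the stack with the depositing sand:mud
    ratio; erosion consumes species volume top-down; all changes are scaled
    by the morphological acceleration factor.  Non-erodible cells are
    floored (no erosion).
    """
    p = cfg or SedimentConfig()
    dep_mud = np.asarray(dep_mud, dtype=float)
    ero_mud = np.where(bed.non_erodible, 0.0, np.asarray(ero_mud, dtype=float))
    dep_sand = np.asarray(dep_sand, dtype=float)
    ero_sand = np.where(bed.non_erodible, 0.0, np.asarray(ero_sand, dtype=float))
    dvol_mud = morfac * dt * (dep_mud - ero_mud) / p.rho_dry_mud
    dvol_sand = morfac * dt * (dep_sand - ero_sand) / p.rho_dry_sand
    mud_avail, sand_avail = bed.species_volumes()
    if np.any(-dvol_mud > mud_avail + 1e-12) or np.any(-dvol_sand > sand_avail + 1e-12):
        raise ValueError("erosion exceeds the tracked substrate stack")
    short = bed.apply_season(dvol_mud, dvol_sand, p)
    if short > 1e-9:
        raise ValueError("erosion exceeds the tracked substrate stack")
    return bed


def mud_fraction_top1m(bed: BedState) -> np.ndarray:
    """Thickness-weighted mean mud fraction of the top metre of substrate."""
    _, _, _, top1m = bed.summaries(SedimentConfig().active_layer)
    return top1m
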