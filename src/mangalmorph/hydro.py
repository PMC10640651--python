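"""Depth-averaged tidal flow over evolving bathymetry.

Vegetation enters the momentum balance twice, following the Baptist
decomposition: a representative bed Chezy value ``C_r`` (which *lowers* the
bed shear stress felt by the sediment under a canopy) and an additional
quadratic momentum sink ``-(lambda/2) u |u|`` (which raises the total flow
resistance).  The solver itself lives in :mod:`mangalmorph._kernels`; this
module provides the public operations and a small wrapper class used by the
scenario engine and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .config import HydroConfig, SedimentConfig


# ---------------------------------------------------------------------------
# roughness closures
# ---------------------------------------------------------------------------

def baptist_roughness(n, h_v, h, cb=65.0, cd=1.0, g=9.81, kappa=0.41):
    """Representative Chezy value (m^1/2/s) for a single vegetation class.

    For submerged vegetation (h >= h_v):
    ``C_r = C_b + (sqrt(g)/kappa) ln(h/h_v) sqrt(1 + C_D n h_v C_b^2 / (2g))``;
    for emergent vegetation (h < h_v) the bed value ``C_b`` is returned.
    ``n = m D`` is the vegetation density (m/m2).
    """
    n = np.asarray(n, dtype=float)
    h = np.asarray(h, dtype=float)
    h_v = np.asarray(h_v, dtype=float)
    if np.any(h <= 0):
        raise ValueError("water depth must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (np.sqrt(g) / kappa) * np.log(h / h_v) * np.sqrt(
            1.0 + cd * n * h_v * cb**2 / (2.0 * g))
    cr = np.where((h >= h_v) & (n > 0) & (h_v > 0), cb + term, cb)
    return cr if cr.ndim else float(cr)


def vegetation_lambda(n, h_v, h, cr, cb=65.0, cd=1.0):
    """Vegetation resistance coefficient lambda (1/m) of the momentum sink.

    ``lambda = C_D n (h_v/h) (C_b/C_r)^2`` when submerged, ``C_D n`` when
    emergent.  Vanishes with the vegetation density.
    """
    n = np.asarray(n, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("water depth must be positive")
    lam = np.where(h >= h_v, cd * n * (h_v / h) * (cb / np.asarray(cr)) ** 2,
                   cd * n)
    lam = np.where(n > 0, lam, 0.0)
    return lam if lam.ndim else float(lam)


def combined_roughness(classes, h, cb=65.0, cd=1.0, g=9.81, kappa=0.41):
    """Combine multiple vegetation classes sharing one cell.

    ``classes`` is a sequence of ``(h_v, n)`` pairs.  Classes are applied
    sequentially in order of object height, each submerged class taking the
    previous C_r as its bed value; lambda contributions are additive.
    Returns ``(C_r, lambda)`` scalars for scalar ``h``.
    """
    if np.any(np.asarray(h) <= 0):
        raise ValueError("water depth must be positive")
    ordered = sorted(classes, key=lambda cl: cl[0])
    cr = cb
    for h_v, n in ordered:
        if n > 0 and h >= h_v and h_v > 0:
            cr = cr + (np.sqrt(g) / kappa) * np.log(h / h_v) * np.sqrt(
                1.0 + cd * n * h_v * cr**2 / (2.0 * g))
    lam = 0.0
    for h_v, n in ordered:
        if n <= 0:
            continue
        lam += cd * n * (h_v / h) * (cb / cr) ** 2 if h >= h_v else cd * n
    return float(cr), float(lam)


def bed_shear_stress(u, v, cr, rho_w=1025.0, g=9.81):
    """Bed shear stress tau = rho g (u^2+v^2) / C_r^2 (N/m2), cell centred."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return rho_w * g * (u**2 + v**2) / np.asarray(cr, dtype=float) ** 2


# ---------------------------------------------------------------------------
# cycle diagnostics
# ---------------------------------------------------------------------------

def hydroperiod(eta_series, z, threshold=0.0, dt=None, period=None):
    """Relative hydroperiod in [0, 1] from a water-level series.

    ``eta_series`` has time on axis 0 and is assumed to span (at least) one
    full tidal cycle; crossings between samples are interpolated linearly so
    closed-form sinusoid results are recovered.  A cell is inundated when
    ``eta - z > threshold``.
    """
    eta = np.asarray(eta_series, dtype=float)
    if eta.shape[0] < 3:
        raise ValueError("need a series spanning a tidal cycle")
    if dt is not None and period is not None and (eta.shape[0] - 1) * dt < period:
        raise ValueError("series shorter than one tidal cycle")
    h = eta - np.asarray(z, dtype=float)
    h0 = h[:-1] - threshold
    h1 = h[1:] - threshold
    w0 = h0 > 0
    w1 = h1 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_dry_to_wet = np.where(h1 != h0, h1 / (h1 - h0), 0.0)
        frac_wet_to_dry = np.where(h1 != h0, h0 / (h0 - h1), 0.0)
    wet = np.where(w0 & w1, 1.0,
                   np.where(w0 & ~w1, frac_wet_to_dry,
                            np.where(w1 & ~w0, frac_dry_to_wet, 0.0)))
    return wet.mean(axis=0)


def tidal_prism(q_series, dt):
    """Tidal prism (m3): flood-directed inlet volume over one cycle.

    The flood side is selected by magnitude, so the result is invariant to
    the sign convention of the discharge series.
    """
    q = np.asarray(q_series, dtype=float)
    pos = float(q[q > 0].sum()) * dt
    neg = float(-q[q < 0].sum()) * dt
    return max(pos, neg)


# ---------------------------------------------------------------------------
# solver wrapper
# ---------------------------------------------------------------------------

@dataclass
class FlowState:
    """Water level, face velocities and the wet mask of the staggered grid."""

    eta: np.ndarray            # (ny, nx) water level (m MSL)
    u: np.ndarray              # (ny, nx+1) x-face velocity (m/s)
    v: np.ndarray              # (ny+1, nx) y-face velocity (m/s)

    @classmethod
    def at_rest(cls, ny, nx, level=0.0):
        return cls(eta=np.full((ny, nx), float(level)),
                   u=np.zeros((ny, nx + 1)), v=np.zeros((ny + 1, nx)))

    def depth(self, z):
        return np.maximum(self.eta - z, 0.0)

    def wet(self, z, threshold=0.05):
        return self.depth(z) > threshold

    def cell_velocity(self):
        uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
        vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
        return uc, vc


class ShallowWater:
    """Hydrodynamics-only driver around the compiled burst kernel.

    Used directly by the flow tests (steady-channel and conservation
    oracles); the coupled scenario engine drives the same kernel with the
    morphodynamic terms switched on.
    """

    def __init__(self, z, forced, qsrc=None, dx=60.0, dy=None,
                 cfg: HydroConfig | None = None, tide_amplitude=0.0,
                 omega=0.0, veg=None):
        self.cfg = cfg or HydroConfig()
        self.z = np.asarray(z, dtype=float).copy()
        ny, nx = self.z.shape
        self.forced = np.ascontiguousarray(forced, dtype=np.bool_)
        self.qsrc = np.zeros((ny, nx)) if qsrc is None else np.asarray(qsrc, dtype=float)
        self.dx = float(dx)
        self.dy = float(dy if dy is not None else dx)
        self.tide_amplitude = float(tide_amplitude)
        self.omega = float(omega)
        self.flow = FlowState.at_rest(ny, nx)
        self.flow.eta[:] = np.maximum(0.0, self.z)  # dry where bed above MSL
        if veg is None:
            zz = np.zeros((ny, nx))
            veg = (zz, zz, zz, zz)
        self.hv1, self.n1, self.hv2, self.n2 = (np.asarray(a, dtype=float) for a in veg)
        self.t = 0.0
        self._parity = 0
        self.m_mud = np.zeros((ny, nx))
        self.m_sand = np.zeros((ny, nx))
        self.ledger = np.zeros(K.LED_N)
        self._sed = SedimentConfig()

    def volume(self):
        """Water volume of the non-forced part of the domain (m3)."""
        h = np.maximum(self.flow.eta - self.z, 0.0)
        return float(h[~self.forced].sum()) * self.dx * self.dy

    def run(self, nsteps, dt=None, collect_eta=False):
        """Advance nsteps; optionally return the per-step eta history."""
        cfg = self.cfg
        dt = float(dt if dt is not None else cfg.dt)
        ny, nx = self.z.shape
        zeros = np.zeros((ny, nx))
        false = np.zeros((ny, nx), dtype=np.bool_)
        history = []
        s = self._sed
        for _ in range(nsteps):
            self.t = K.simulate_burst(
                self.flow.eta, self.flow.u, self.flow.v, self.z,
                self.forced, self.qsrc,
                self.hv1, self.n1, self.hv2, self.n2,
                self.m_mud, self.m_sand,
                zeros, zeros, zeros, zeros, false,
                zeros, zeros, zeros, zeros, zeros, zeros,
                1, dt, self.t, self.tide_amplitude, self.omega,
                self.dx, self.dy,
                cfg.g, cfg.kappa, cfg.chezy_bare, cfg.drag_coefficient,
                cfg.rho_water, cfg.dry_depth, cfg.theta,
                cfg.velocity_smoothing, 0.0,
                0.0, s.tau_ce, s.tau_cd, 0.0, 0.0, 0.0, s.sand_ucrit**2,
                0.0, 0.0, 0.0, s.rho_dry_mud, s.rho_dry_sand,
                1.0, 0.0, 0.0, 0.0, s.max_bed_change_per_step, 1e9, 10.0,
                -1, 0, 0,
                10**9, cfg.dry_depth, 1, False,
                zeros, zeros, zeros, self.ledger)
            if collect_eta:
                history.append(self.flow.eta.copy())
        return np.array(history) if collect_eta else None


def step_flow(model: ShallowWater, dt=None):
    """Advance a :class:`ShallowWater` model by a single step."""
    model.run(1, dt=dt)
    return model.flow
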