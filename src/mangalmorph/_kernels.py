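"""Compiled numerical kernels.

Flow is advanced with a Strang-split semi-implicit scheme on a staggered
C-grid: a half y-sweep on either side of a full x-sweep, each sweep solving
the free-surface/continuity coupling implicitly along its grid lines
(theta-weighted, Casulli-style) with implicit bed friction, which removes
the surface gravity-wave CFL restriction.  Momentum advection is omitted
(short, friction-dominated basin); a weak lateral momentum-exchange filter
stands in for eddy viscosity and suppresses grid-scale noise at the inlet
constriction.  Continuity is discretized in flux form, so water volume is
conserved to round-off; a per-cell outflux limiter with inflow credit keeps
depths non-negative without breaking the flux-form budget.

Suspended mud and sand are advected with the accumulated face volume fluxes
of the flow (donor-cell upwind) on a small stride of hydrodynamic steps;
per-cell caps keep tracer masses non-negative, so the sediment budget
closes exactly against the boundary ledgers.

All kernels operate on plain float64 arrays of shape (ny, nx); u lives on
x-faces (ny, nx+1), v on y-faces (ny+1, nx).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ledger slots (hydrodynamic-time units unless noted)
LED_VOL_BND = 0      # water volume through open boundary, + into domain (m3)
LED_VOL_RIV = 1      # river water volume added (m3)
LED_MUD_BND = 2      # suspended mud mass through boundary, + in (kg)
LED_SAND_BND = 3     # suspended sand mass through boundary, + in (kg)
LED_MUD_RIV = 4      # river mud mass added (kg)
LED_SAND_RIV = 5     # river sand mass added (kg)
LED_TP_FLOOD = 6     # landward inlet volume during the diagnostic cycle (m3)
LED_TP_EBB = 7       # seaward inlet volume during the diagnostic cycle (m3)
LED_BL_BND = 8       # bed-load sand volume through boundary, + in (m3, morphological)
LED_N = 9


@njit(cache=True, fastmath=True)
def veg_cr_lam(h, hv1, n1, hv2, n2, cb, cd, g, kappa):
    """Baptist representative Chezy and resistance coefficient for one cell.

    Two object classes (pneumatophores, stems) are combined sequentially in
    order of object height: each submerged class takes the previous C_r as
    its bed value.  Lambda contributions are additive; emergent classes
    contribute C_D * n.
    """
    cr = cb
    sg = math.sqrt(g) / kappa
    if n1 > 0.0 and h >= hv1 and hv1 > 0.0:
        cr = cr + sg * math.log(h / hv1) * math.sqrt(1.0 + cd * n1 * hv1 * cr * cr / (2.0 * g))
    if n2 > 0.0 and h >= hv2 and hv2 > 0.0:
        cr = cr + sg * math.log(h / hv2) * math.sqrt(1.0 + cd * n2 * hv2 * cr * cr / (2.0 * g))
    lam = 0.0
    if n1 > 0.0:
        if h >= hv1:
            lam += cd * n1 * (hv1 / h) * (cb * cb) / (cr * cr)
        else:
            lam += cd * n1
    if n2 > 0.0:
        if h >= hv2:
            lam += cd * n2 * (hv2 / h) * (cb * cb) / (cr * cr)
        else:
            lam += cd * n2
    return cr, lam


@njit(cache=True, fastmath=True)
def _roughness_fields(eta, z, hv1, n1, hv2, n2, cb, cd, g, kappa, cr_c, lam_c):
    ny, nx = eta.shape
    for j in range(ny):
        for i in range(nx):
            h = eta[j, i] - z[j, i]
            if h > 1e-9 and (n1[j, i] > 0.0 or n2[j, i] > 0.0):
                cr, lam = veg_cr_lam(h, hv1[j, i], n1[j, i], hv2[j, i], n2[j, i],
                                     cb, cd, g, kappa)
            else:
                cr, lam = cb, 0.0
            cr_c[j, i] = cr
            lam_c[j, i] = lam


@njit(cache=True, fastmath=True)
def _thomas(a, b, c, d, n, x, cp, dp):
    """Solve a tridiagonal system of size n (a sub-, b main, c super-diag)."""
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        m = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / m
        dp[i] = (d[i] - a[i] * dp[i - 1]) / m
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]


@njit(cache=True, fastmath=True)
def _sub_step_x(eta, u, v, z, forced, qsrc, cr_c, lam_c,
                dth, qfrac, theta, dx, dy, g, h_dry,
                fx_acc, diag_on, inlet_i, inlet_j0, inlet_j1, ledger):
    """Theta-implicit x-sweep over one interval dth.

    Advances eta and u in flux form, accumulates the realized face volume
    fluxes into ``fx_acc`` (consumed later by the tracer transport), and
    books boundary/inlet volumes.
    """
    ny, nx = eta.shape
    area = dx * dy

    h_old = np.empty((ny, nx))
    for j in range(ny):
        for i in range(nx):
            h = eta[j, i] - z[j, i]
            h_old[j, i] = h if h > 0.0 else 0.0

    hu = np.zeros((ny, nx + 1))
    alpha = np.zeros((ny, nx + 1))
    uexp = np.zeros((ny, nx + 1))   # explicit part of the new face velocity
    uflx = np.zeros((ny, nx + 1))   # explicit part of the flux velocity
    for j in range(ny):
        for i in range(1, nx):
            d = max(eta[j, i - 1], eta[j, i]) - max(z[j, i - 1], z[j, i])
            if d > h_dry:
                vbar = 0.25 * (v[j, i - 1] + v[j + 1, i - 1] + v[j, i] + v[j + 1, i])
                sp = math.sqrt(u[j, i] * u[j, i] + vbar * vbar)
                crf = 0.5 * (cr_c[j, i - 1] + cr_c[j, i])
                lamf = 0.5 * (lam_c[j, i - 1] + lam_c[j, i])
                fr = 1.0 + dth * (g * sp / (crf * crf * d) + 0.5 * lamf * sp)
                hu[j, i] = d
                alpha[j, i] = g * theta * dth / (dx * fr)
                ue = (u[j, i] - g * (1.0 - theta) * dth / dx
                      * (eta[j, i] - eta[j, i - 1])) / fr
                uexp[j, i] = ue
                uflx[j, i] = theta * ue + (1.0 - theta) * u[j, i]
            else:
                u[j, i] = 0.0
        u[j, 0] = 0.0
        u[j, nx] = 0.0

    # tridiagonal solve per row (forced cells enter as Dirichlet rows)
    etas = np.empty((ny, nx))
    a = np.empty(nx)
    b = np.empty(nx)
    c = np.empty(nx)
    d_ = np.empty(nx)
    x = np.empty(nx)
    cp = np.empty(nx)
    dp = np.empty(nx)
    for j in range(ny):
        for i in range(nx):
            if forced[j, i]:
                a[i] = 0.0
                b[i] = 1.0
                c[i] = 0.0
                d_[i] = eta[j, i]
            else:
                aw = dth / dx * hu[j, i] * theta * alpha[j, i]
                ae = dth / dx * hu[j, i + 1] * theta * alpha[j, i + 1]
                a[i] = -aw
                b[i] = 1.0 + aw + ae
                c[i] = -ae
                d_[i] = (eta[j, i]
                         + dth / dx * (hu[j, i] * uflx[j, i] - hu[j, i + 1] * uflx[j, i + 1])
                         + qfrac * qsrc[j, i] * dth / area)
        _thomas(a, b, c, d_, nx, x, cp, dp)
        for i in range(nx):
            etas[j, i] = x[i]

    # face volume fluxes from the theta-weighted velocity
    flux = np.zeros((ny, nx + 1))
    for j in range(ny):
        for i in range(1, nx):
            if hu[j, i] > 0.0:
                uf = uflx[j, i] - theta * alpha[j, i] * (etas[j, i] - etas[j, i - 1])
                flux[j, i] = hu[j, i] * uf * dth * dy

    # positivity limiter with inflow credit over the (few) limited cells
    scale = np.ones((ny, nx))
    lim_j = np.empty(ny * nx, dtype=np.int64)
    lim_i = np.empty(ny * nx, dtype=np.int64)
    nlim = 0
    for j in range(ny):
        for i in range(nx):
            if forced[j, i]:
                continue
            vout = 0.0
            if flux[j, i] < 0.0:
                vout -= flux[j, i]
            if flux[j, i + 1] > 0.0:
                vout += flux[j, i + 1]
            vavail = h_old[j, i] * area + qfrac * qsrc[j, i] * dth
            if vout > vavail:
                scale[j, i] = vavail / vout if vout > 0.0 else 0.0
                lim_j[nlim] = j
                lim_i[nlim] = i
                nlim += 1
    if nlim > 0:
        for _ in range(3):
            changed = False
            for k in range(nlim):
                j = lim_j[k]
                i = lim_i[k]
                if scale[j, i] >= 1.0:
                    continue
                vout = 0.0
                vin = 0.0
                fw = flux[j, i]
                fe = flux[j, i + 1]
                if fw < 0.0:
                    vout -= fw
                elif fw > 0.0:
                    sw_ = scale[j, i - 1] if (i > 0 and not forced[j, i - 1]) else 1.0
                    vin += fw * sw_
                if fe > 0.0:
                    vout += fe
                elif fe < 0.0:
                    se_ = scale[j, i + 1] if (i < nx - 1 and not forced[j, i + 1]) else 1.0
                    vin -= fe * se_
                vavail = h_old[j, i] * area + qfrac * qsrc[j, i] * dth + vin
                if vout > 0.0:
                    s_new = min(1.0, vavail / vout)
                    if s_new > scale[j, i]:
                        scale[j, i] = s_new
                        changed = True
            if not changed:
                break
        for k in range(nlim):
            j = lim_j[k]
            i = lim_i[k]
            s = scale[j, i]
            if s < 1.0:
                if flux[j, i] < 0.0:
                    flux[j, i] *= s
                if flux[j, i + 1] > 0.0:
                    flux[j, i + 1] *= s

    # update water levels (flux form), face velocities, accumulators
    for j in range(ny):
        for i in range(nx):
            if not forced[j, i]:
                eta[j, i] += (flux[j, i] - flux[j, i + 1]) / area + qfrac * qsrc[j, i] * dth / area
                ledger[LED_VOL_RIV] += qfrac * qsrc[j, i] * dth
        for i in range(1, nx):
            f = flux[j, i]
            if hu[j, i] > 0.0:
                u[j, i] = f / (hu[j, i] * dth * dy)
            if f != 0.0:
                fx_acc[j, i] += f
                if forced[j, i - 1] != forced[j, i]:
                    ledger[LED_VOL_BND] += f if forced[j, i - 1] else -f
                if diag_on and i == inlet_i and inlet_j0 <= j < inlet_j1:
                    if f > 0.0:
                        ledger[LED_TP_FLOOD] += f
                    else:
                        ledger[LED_TP_EBB] -= f


@njit(cache=True, fastmath=True)
def _sub_step_y(eta, u, v, z, forced, qsrc, cr_c, lam_c,
                dth, qfrac, theta, dx, dy, g, h_dry, fy_acc, ledger):
    """Theta-implicit y-sweep; mirror of the x-sweep."""
    ny, nx = eta.shape
    area = dx * dy

    h_old = np.empty((ny, nx))
    for j in range(ny):
        for i in range(nx):
            h = eta[j, i] - z[j, i]
            h_old[j, i] = h if h > 0.0 else 0.0

    hv = np.zeros((ny + 1, nx))
    alpha = np.zeros((ny + 1, nx))
    vexp = np.zeros((ny + 1, nx))
    vflx = np.zeros((ny + 1, nx))
    for i in range(nx):
        for j in range(1, ny):
            d = max(eta[j - 1, i], eta[j, i]) - max(z[j - 1, i], z[j, i])
            if d > h_dry:
                ubar = 0.25 * (u[j - 1, i] + u[j - 1, i + 1] + u[j, i] + u[j, i + 1])
                sp = math.sqrt(v[j, i] * v[j, i] + ubar * ubar)
                crf = 0.5 * (cr_c[j - 1, i] + cr_c[j, i])
                lamf = 0.5 * (lam_c[j - 1, i] + lam_c[j, i])
                fr = 1.0 + dth * (g * sp / (crf * crf * d) + 0.5 * lamf * sp)
                hv[j, i] = d
                alpha[j, i] = g * theta * dth / (dy * fr)
                ve = (v[j, i] - g * (1.0 - theta) * dth / dy
                      * (eta[j, i] - eta[j - 1, i])) / fr
                vexp[j, i] = ve
                vflx[j, i] = theta * ve + (1.0 - theta) * v[j, i]
            else:
                v[j, i] = 0.0
        v[0, i] = 0.0
        v[ny, i] = 0.0

    etas = np.empty((ny, nx))
    a = np.empty(ny)
    b = np.empty(ny)
    c = np.empty(ny)
    d_ = np.empty(ny)
    x = np.empty(ny)
    cp = np.empty(ny)
    dp = np.empty(ny)
    for i in range(nx):
        for j in range(ny):
            if forced[j, i]:
                a[j] = 0.0
                b[j] = 1.0
                c[j] = 0.0
                d_[j] = eta[j, i]
            else:
                as_ = dth / dy * hv[j, i] * theta * alpha[j, i]
                an = dth / dy * hv[j + 1, i] * theta * alpha[j + 1, i]
                a[j] = -as_
                b[j] = 1.0 + as_ + an
                c[j] = -an
                d_[j] = (eta[j, i]
                         + dth / dy * (hv[j, i] * vflx[j, i] - hv[j + 1, i] * vflx[j + 1, i])
                         + qfrac * qsrc[j, i] * dth / area)
        _thomas(a, b, c, d_, ny, x, cp, dp)
        for j in range(ny):
            etas[j, i] = x[j]

    flux = np.zeros((ny + 1, nx))
    for i in range(nx):
        for j in range(1, ny):
            if hv[j, i] > 0.0:
                vf = vflx[j, i] - theta * alpha[j, i] * (etas[j, i] - etas[j - 1, i])
                flux[j, i] = hv[j, i] * vf * dth * dx

    scale = np.ones((ny, nx))
    lim_j = np.empty(ny * nx, dtype=np.int64)
    lim_i = np.empty(ny * nx, dtype=np.int64)
    nlim = 0
    for i in range(nx):
        for j in range(ny):
            if forced[j, i]:
                continue
            vout = 0.0
            if flux[j, i] < 0.0:
                vout -= flux[j, i]
            if flux[j + 1, i] > 0.0:
                vout += flux[j + 1, i]
            vavail = h_old[j, i] * area + qfrac * qsrc[j, i] * dth
            if vout > vavail:
                scale[j, i] = vavail / vout if vout > 0.0 else 0.0
                lim_j[nlim] = j
                lim_i[nlim] = i
                nlim += 1
    if nlim > 0:
        for _ in range(3):
            changed = False
            for k in range(nlim):
                j = lim_j[k]
                i = lim_i[k]
                if scale[j, i] >= 1.0:
                    continue
                vout = 0.0
                vin = 0.0
                fs = flux[j, i]
                fn = flux[j + 1, i]
                if fs < 0.0:
                    vout -= fs
                elif fs > 0.0:
                    ss_ = scale[j - 1, i] if (j > 0 and not forced[j - 1, i]) else 1.0
                    vin += fs * ss_
                if fn > 0.0:
                    vout += fn
                elif fn < 0.0:
                    sn_ = scale[j + 1, i] if (j < ny - 1 and not forced[j + 1, i]) else 1.0
                    vin -= fn * sn_
                vavail = h_old[j, i] * area + qfrac * qsrc[j, i] * dth + vin
                if vout > 0.0:
                    s_new = min(1.0, vavail / vout)
                    if s_new > scale[j, i]:
                        scale[j, i] = s_new
                        changed = True
            if not changed:
                break
        for k in range(nlim):
            j = lim_j[k]
            i = lim_i[k]
            s = scale[j, i]
            if s < 1.0:
                if flux[j, i] < 0.0:
                    flux[j, i] *= s
                if flux[j + 1, i] > 0.0:
                    flux[j + 1, i] *= s

    for i in range(nx):
        for j in range(ny):
            if not forced[j, i]:
                eta[j, i] += (flux[j, i] - flux[j + 1, i]) / area + qfrac * qsrc[j, i] * dth / area
                ledger[LED_VOL_RIV] += qfrac * qsrc[j, i] * dth
        for j in range(1, ny):
            f = flux[j, i]
            if hv[j, i] > 0.0:
                v[j, i] = f / (hv[j, i] * dth * dx)
            if f != 0.0:
                fy_acc[j, i] += f
                if forced[j - 1, i] != forced[j, i]:
                    ledger[LED_VOL_BND] += f if forced[j - 1, i] else -f


@njit(cache=True, fastmath=True)
def _smooth_velocities(u, v, gamma):
    """Weak lateral momentum exchange (eddy-viscosity surrogate).

    Blends each open face velocity with the mean of its open neighbours;
    closed/dry faces (velocity exactly zero) are untouched and excluded from
    the averages.  A uniform field is invariant, so steady uniform-flow
    balances are preserved; grid-scale velocity noise (which the split
    scheme does not otherwise damp, having no advection or viscous terms)
    is removed.
    """
    ny, nxp1 = u.shape
    nx = nxp1 - 1
    un = u.copy()
    for j in range(ny):
        for i in range(1, nx):
            if un[j, i] == 0.0:
                continue
            s = 0.0
            n = 0
            if j > 0 and un[j - 1, i] != 0.0:
                s += un[j - 1, i]
                n += 1
            if j < ny - 1 and un[j + 1, i] != 0.0:
                s += un[j + 1, i]
                n += 1
            if un[j, i - 1] != 0.0:
                s += un[j, i - 1]
                n += 1
            if i < nx - 1 and un[j, i + 1] != 0.0:
                s += un[j, i + 1]
                n += 1
            if n > 0:
                u[j, i] = (1.0 - gamma) * un[j, i] + gamma * s / n
    vn = v.copy()
    for j in range(1, ny):
        for i in range(nx):
            if vn[j, i] == 0.0:
                continue
            s = 0.0
            n = 0
            if i > 0 and vn[j, i - 1] != 0.0:
                s += vn[j, i - 1]
                n += 1
            if i < nx - 1 and vn[j, i + 1] != 0.0:
                s += vn[j, i + 1]
                n += 1
            if vn[j - 1, i] != 0.0:
                s += vn[j - 1, i]
                n += 1
            if j < ny - 1 and vn[j + 1, i] != 0.0:
                s += vn[j + 1, i]
                n += 1
            if n > 0:
                v[j, i] = (1.0 - gamma) * vn[j, i] + gamma * s / n


@njit(cache=True, fastmath=True)
def _transport_tracers(eta, u, v, z, forced, m_mud, m_sand, fx, fy,
                       c_mud_bc, ks, ucr2, dx, dy, ledger):
    """Advect the depth-integrated tracers with accumulated volume fluxes.

    Donor-cell upwind on the net face volumes; each cell's outgoing tracer
    mass is capped at what it holds, which keeps masses non-negative and
    the mass budget exact.  Open-boundary donors carry the ambient mud
    concentration (default 0: exported mud does not re-enter) and the local
    equilibrium sand concentration.
    """
    ny, nx = eta.shape
    area = dx * dy
    mfm_x = np.zeros((ny, nx + 1))
    mfs_x = np.zeros((ny, nx + 1))
    mfm_y = np.zeros((ny + 1, nx))
    mfs_y = np.zeros((ny + 1, nx))

    for j in range(ny):
        for i in range(1, nx):
            f = fx[j, i]
            if f == 0.0:
                continue
            dj, di = (j, i - 1) if f > 0.0 else (j, i)
            if forced[dj, di]:
                cm = c_mud_bc
                uf = abs(u[j, i])
                ex = uf * uf - ucr2
                hb = eta[dj, di] - z[dj, di]
                if hb < 0.5:
                    hb = 0.5
                cs = ks * ex * math.sqrt(ex) / hb if ex > 0.0 else 0.0
            else:
                hd = eta[dj, di] - z[dj, di]
                if hd > 1e-9:
                    cm = m_mud[dj, di] / hd
                    cs = m_sand[dj, di] / hd
                else:
                    cm = 0.0
                    cs = 0.0
            mfm_x[j, i] = f * cm
            mfs_x[j, i] = f * cs
    for i in range(nx):
        for j in range(1, ny):
            f = fy[j, i]
            if f == 0.0:
                continue
            dj = j - 1 if f > 0.0 else j
            if forced[dj, i]:
                cm = c_mud_bc
                vf = abs(v[j, i])
                ex = vf * vf - ucr2
                hb = eta[dj, i] - z[dj, i]
                if hb < 0.5:
                    hb = 0.5
                cs = ks * ex * math.sqrt(ex) / hb if ex > 0.0 else 0.0
            else:
                hd = eta[dj, i] - z[dj, i]
                if hd > 1e-9:
                    cm = m_mud[dj, i] / hd
                    cs = m_sand[dj, i] / hd
                else:
                    cm = 0.0
                    cs = 0.0
            mfm_y[j, i] = f * cm
            mfs_y[j, i] = f * cs

    # cap outgoing mass at the donor's stored mass (all four faces)
    for j in range(ny):
        for i in range(nx):
            if forced[j, i]:
                continue
            out_m = 0.0
            out_s = 0.0
            if mfm_x[j, i] < 0.0:
                out_m -= mfm_x[j, i]
            if mfm_x[j, i + 1] > 0.0:
                out_m += mfm_x[j, i + 1]
            if mfm_y[j, i] < 0.0:
                out_m -= mfm_y[j, i]
            if mfm_y[j + 1, i] > 0.0:
                out_m += mfm_y[j + 1, i]
            if mfs_x[j, i] < 0.0:
                out_s -= mfs_x[j, i]
            if mfs_x[j, i + 1] > 0.0:
                out_s += mfs_x[j, i + 1]
            if mfs_y[j, i] < 0.0:
                out_s -= mfs_y[j, i]
            if mfs_y[j + 1, i] > 0.0:
                out_s += mfs_y[j + 1, i]
            am = m_mud[j, i] * area
            if out_m > am:
                sm = am / out_m if out_m > 0.0 else 0.0
                if mfm_x[j, i] < 0.0:
                    mfm_x[j, i] *= sm
                if mfm_x[j, i + 1] > 0.0:
                    mfm_x[j, i + 1] *= sm
                if mfm_y[j, i] < 0.0:
                    mfm_y[j, i] *= sm
                if mfm_y[j + 1, i] > 0.0:
                    mfm_y[j + 1, i] *= sm
            as_ = m_sand[j, i] * area
            if out_s > as_:
                ss = as_ / out_s if out_s > 0.0 else 0.0
                if mfs_x[j, i] < 0.0:
                    mfs_x[j, i] *= ss
                if mfs_x[j, i + 1] > 0.0:
                    mfs_x[j, i + 1] *= ss
                if mfs_y[j, i] < 0.0:
                    mfs_y[j, i] *= ss
                if mfs_y[j + 1, i] > 0.0:
                    mfs_y[j + 1, i] *= ss

    for j in range(ny):
        for i in range(1, nx):
            mm = mfm_x[j, i]
            ms = mfs_x[j, i]
            if mm == 0.0 and ms == 0.0:
                continue
            if not forced[j, i - 1]:
                m_mud[j, i - 1] -= mm / area
                m_sand[j, i - 1] -= ms / area
            if not forced[j, i]:
                m_mud[j, i] += mm / area
                m_sand[j, i] += ms / area
            if forced[j, i - 1] != forced[j, i]:
                sgn = 1.0 if forced[j, i - 1] else -1.0
                ledger[LED_MUD_BND] += sgn * mm
                ledger[LED_SAND_BND] += sgn * ms
    for i in range(nx):
        for j in range(1, ny):
            mm = mfm_y[j, i]
            ms = mfs_y[j, i]
            if mm == 0.0 and ms == 0.0:
                continue
            if not forced[j - 1, i]:
                m_mud[j - 1, i] -= mm / area
                m_sand[j - 1, i] -= ms / area
            if not forced[j, i]:
                m_mud[j, i] += mm / area
                m_sand[j, i] += ms / area
            if forced[j - 1, i] != forced[j, i]:
                sgn = 1.0 if forced[j - 1, i] else -1.0
                ledger[LED_MUD_BND] += sgn * mm
                ledger[LED_SAND_BND] += sgn * ms
    for j in range(ny):
        for i in range(nx):
            if m_mud[j, i] < 0.0:
                m_mud[j, i] = 0.0
            if m_sand[j, i] < 0.0:
                m_sand[j, i] = 0.0


@njit(cache=True, fastmath=True)
def _add_river_tracers(eta, z, forced, qsrc, m_mud, m_sand,
                       c_river, c_sand_river, dt, area, ledger):
    """Inject the river sediment load into the water column.

    Runs immediately before the transport pass so a fresh injection can be
    flushed out of the small mouth cell within the same interval instead of
    settling there first.
    """
    ny, nx = eta.shape
    for j in range(ny):
        for i in range(nx):
            if qsrc[j, i] > 0.0 and not forced[j, i]:
                src_m = qsrc[j, i] * c_river * dt / area
                m_mud[j, i] += src_m
                ledger[LED_MUD_RIV] += src_m * area
                if c_sand_river > 0.0:
                    src_s = qsrc[j, i] * c_sand_river * dt / area
                    m_sand[j, i] += src_s
                    ledger[LED_SAND_RIV] += src_s * area


@njit(cache=True, fastmath=True)
def _diffuse(m, eta, z, forced, diff, dt, dx, dy, h_dry):
    """Conservative horizontal mixing of a depth-integrated tracer.

    Each face exchange is capped at a fifth of the donor cell's mass so the
    explicit update stays positive and stable even across sharp depth steps
    (where the face depth can greatly exceed the shallow cell's own depth).
    """
    ny, nx = m.shape
    dmx = np.zeros((ny, nx))
    for j in range(ny):
        for i in range(nx - 1):
            hl = eta[j, i] - z[j, i]
            hr = eta[j, i + 1] - z[j, i + 1]
            if hl > h_dry and hr > h_dry and not forced[j, i] and not forced[j, i + 1]:
                hf = 0.5 * (hl + hr)
                f = diff * hf * (m[j, i + 1] / hr - m[j, i] / hl) / dx * dt
                if f > 0.0:
                    cap = 0.2 * m[j, i + 1]
                    if f > cap:
                        f = cap
                else:
                    cap = 0.2 * m[j, i]
                    if -f > cap:
                        f = -cap
                dmx[j, i] += f
                dmx[j, i + 1] -= f
    for i in range(nx):
        for j in range(ny - 1):
            hl = eta[j, i] - z[j, i]
            hr = eta[j + 1, i] - z[j + 1, i]
            if hl > h_dry and hr > h_dry and not forced[j, i] and not forced[j + 1, i]:
                hf = 0.5 * (hl + hr)
                f = diff * hf * (m[j + 1, i] / hr - m[j, i] / hl) / dy * dt
                if f > 0.0:
                    cap = 0.2 * m[j + 1, i]
                    if f > cap:
                        f = cap
                else:
                    cap = 0.2 * m[j, i]
                    if -f > cap:
                        f = -cap
                dmx[j, i] += f
                dmx[j + 1, i] -= f
    for j in range(ny):
        for i in range(nx):
            m[j, i] += dmx[j, i]
            if m[j, i] < 0.0:
                m[j, i] = 0.0


@njit(cache=True, fastmath=True)
def _morpho_step(eta, u, v, z, forced, qsrc, cr_c, m_mud, m_sand,
                 frac_mud_a, frac_sand_a, avail_mud, avail_sand, nonerod,
                 acc_dmud, acc_emud, acc_dsand, acc_esand, acc_bl, acc_blm,
                 tau_out, dt, dx, dy, g, rho_w, h_dry,
                 m_ero, tau_ce, tau_cd, ws_mud, ws_sand, ks, ucr2,
                 alpha_b, alpha_t, alpha_l, rho_mud, rho_sand,
                 morfac, c_river, c_sand_river, dz_cap, dep_ceiling,
                 crit_slope, ledger):
    """Erosion/deposition exchange, bed-load transport and bed update.

    Bed changes are multiplied by the morphological acceleration factor;
    suspended concentrations see the unscaled exchange fluxes.  Erosion is
    partitioned by the composition of the active surface layer and capped by
    the sediment actually available in the substrate stack; every flux is
    additionally capped so a single accelerated interval cannot move the bed
    by more than ``dz_cap`` (keeps the coupling stable at scour hot-spots).
    """
    ny, nx = eta.shape
    area = dx * dy
    cap_mud = dz_cap * rho_mud / (morfac * dt)    # kg/m2/s per flux term
    cap_sand = dz_cap * rho_sand / (morfac * dt)

    qbx = np.zeros((ny, nx))
    qby = np.zeros((ny, nx))

    for j in range(ny):
        for i in range(nx):
            tau_out[j, i] = 0.0
            if forced[j, i]:
                continue
            h = eta[j, i] - z[j, i]
            if h <= 1e-9:
                if qsrc[j, i] > 0.0 or z[j, i] >= dep_ceiling:
                    continue  # flow-through or above the depositional frame
                # an effectively dry cell settles its remaining load
                d_m = min(m_mud[j, i] / dt, cap_mud)
                d_s = min(m_sand[j, i] / dt, cap_sand)
                if d_m > 0.0 or d_s > 0.0:
                    m_mud[j, i] -= d_m * dt
                    m_sand[j, i] -= d_s * dt
                    avail_mud[j, i] += morfac * dt * d_m / rho_mud
                    avail_sand[j, i] += morfac * dt * d_s / rho_sand
                    acc_dmud[j, i] += morfac * d_m * dt
                    acc_dsand[j, i] += morfac * d_s * dt
                    z[j, i] += morfac * dt * (d_m / rho_mud + d_s / rho_sand)
                continue
            uc = 0.5 * (u[j, i] + u[j, i + 1])
            vc = 0.5 * (v[j, i] + v[j + 1, i])
            sp2 = uc * uc + vc * vc
            cr = cr_c[j, i]
            tau = rho_w * g * sp2 / (cr * cr)
            tau_out[j, i] = tau

            # --- mud exchange (Partheniades-Krone) -----------------------
            e_m = 0.0
            if tau > tau_ce and not nonerod[j, i]:
                e_m = m_ero * (tau / tau_ce - 1.0) * frac_mud_a[j, i]
                cap = avail_mud[j, i] * rho_mud / (morfac * dt)
                if e_m > cap:
                    e_m = cap
                if e_m > cap_mud:
                    e_m = cap_mud
            # deposition integrated implicitly over the interval: a shallow,
            # strongly flushed cell cannot deposit more than an exponential
            # decay of its load allows.  Deposition is confined to the tidal
            # frame: supratidal fluvial levee growth is not modelled, so beds
            # at the ceiling stop accreting (a river would incise there).
            above_frame = z[j, i] >= dep_ceiling
            fac = 1.0 - tau / tau_cd if tau < tau_cd else 0.0
            if fac > 0.0 and m_mud[j, i] > 0.0 and not above_frame:
                d_m = m_mud[j, i] / dt * (1.0 - math.exp(-ws_mud * fac * dt / h))
            else:
                d_m = 0.0
            if d_m > cap_mud:
                d_m = cap_mud
            if e_m != 0.0 or d_m != 0.0:
                m_mud[j, i] += (e_m - d_m) * dt
                avail_mud[j, i] += morfac * dt * (d_m - e_m) / rho_mud
                acc_dmud[j, i] += morfac * d_m * dt
                acc_emud[j, i] += morfac * e_m * dt

            # --- suspended sand (capacity relaxation; capacity falls with
            # depth, which lets channels reach an equilibrium depth) -------
            ex = sp2 - ucr2
            h_ref = h if h > 0.5 else 0.5
            cs_eq = ks * ex * math.sqrt(ex) / h_ref if ex > 0.0 else 0.0
            e_s = 0.0
            if cs_eq > 0.0 and not nonerod[j, i]:
                e_s = ws_sand * cs_eq * frac_sand_a[j, i]
                cap = avail_sand[j, i] * rho_sand / (morfac * dt)
                if e_s > cap:
                    e_s = cap
                if e_s > cap_sand:
                    e_s = cap_sand
            if m_sand[j, i] > 0.0 and not above_frame:
                d_s = m_sand[j, i] / dt * (1.0 - math.exp(-ws_sand * dt / h))
            else:
                d_s = 0.0
            if d_s > cap_sand:
                d_s = cap_sand
            if e_s != 0.0 or d_s != 0.0:
                m_sand[j, i] += (e_s - d_s) * dt
                avail_sand[j, i] += morfac * dt * (d_s - e_s) / rho_sand
                acc_dsand[j, i] += morfac * d_s * dt
                acc_esand[j, i] += morfac * e_s * dt

            z[j, i] += morfac * dt * ((d_m - e_m) / rho_mud + (d_s - e_s) / rho_sand)

            # --- bed-load vector with slope effects ----------------------
            if ex > 0.0 and not nonerod[j, i] and avail_sand[j, i] > 0.0:
                sp = math.sqrt(sp2)
                if sp > 1e-8:
                    mag = alpha_b * ex * math.sqrt(ex) * frac_sand_a[j, i]
                    exn = uc / sp
                    eyn = vc / sp
                    dzdx = 0.0
                    if 0 < i < nx - 1:
                        dzdx = (z[j, i + 1] - z[j, i - 1]) / (2.0 * dx)
                    dzdy = 0.0
                    if 0 < j < ny - 1:
                        dzdy = (z[j + 1, i] - z[j - 1, i]) / (2.0 * dy)
                    s_long = exn * dzdx + eyn * dzdy
                    fac = 1.0 - alpha_l * s_long
                    if fac < 0.0:
                        fac = 0.0
                    elif fac > 2.0:
                        fac = 2.0
                    mag *= fac
                    tx = dzdx - s_long * exn
                    ty = dzdy - s_long * eyn
                    qbx[j, i] = mag * exn - alpha_t * mag * tx
                    qby[j, i] = mag * eyn - alpha_t * mag * ty

    # bed-load divergence via donor-cell face fluxes (morphological volume)
    for j in range(ny):
        for i in range(1, nx):
            qf = 0.5 * (qbx[j, i - 1] + qbx[j, i])
            if qf == 0.0:
                continue
            d = max(eta[j, i - 1], eta[j, i]) - max(z[j, i - 1], z[j, i])
            if d <= h_dry:
                continue
            if qf > 0.0:
                dj, di, rj, ri = j, i - 1, j, i
            else:
                dj, di, rj, ri = j, i, j, i - 1
            if nonerod[dj, di] or forced[dj, di]:
                continue
            vol = abs(qf) * dy * dt * morfac  # m3
            capv = min(0.25 * avail_sand[dj, di], dz_cap) * area
            if vol > capv:
                vol = capv
            dz_d = vol / area
            z[dj, di] -= dz_d
            avail_sand[dj, di] -= dz_d
            acc_bl[dj, di] -= dz_d
            if forced[rj, ri]:
                ledger[LED_BL_BND] -= vol
            else:
                z[rj, ri] += dz_d
                avail_sand[rj, ri] += dz_d
                acc_bl[rj, ri] += dz_d
    for i in range(nx):
        for j in range(1, ny):
            qf = 0.5 * (qby[j - 1, i] + qby[j, i])
            if qf == 0.0:
                continue
            d = max(eta[j - 1, i], eta[j, i]) - max(z[j - 1, i], z[j, i])
            if d <= h_dry:
                continue
            if qf > 0.0:
                dj, rj = j - 1, j
            else:
                dj, rj = j, j - 1
            if nonerod[dj, i] or forced[dj, i]:
                continue
            vol = abs(qf) * dx * dt * morfac
            capv = min(0.25 * avail_sand[dj, i], dz_cap) * area
            if vol > capv:
                vol = capv
            dz_d = vol / area
            z[dj, i] -= dz_d
            avail_sand[dj, i] -= dz_d
            acc_bl[dj, i] -= dz_d
            if forced[rj, i]:
                ledger[LED_BL_BND] -= vol
            else:
                z[rj, i] += dz_d
                avail_sand[rj, i] += dz_d
                acc_bl[rj, i] += dz_d

    # avalanching: relax bed slopes beyond the critical angle by moving bed
    # material (surface-layer composition) downslope; keeps channel walls at
    # a finite angle of repose, which the transport laws alone do not.
    for j in range(ny):
        for i in range(1, nx):
            dzd = z[j, i - 1] - z[j, i]
            if dzd > 0.0:
                dj, di, rj, ri = j, i - 1, j, i
            else:
                dzd = -dzd
                dj, di, rj, ri = j, i, j, i - 1
            if dzd <= crit_slope * dx:
                continue
            if (nonerod[dj, di] or forced[dj, di]
                    or nonerod[rj, ri] or forced[rj, ri]):
                continue
            move = 0.25 * (dzd - crit_slope * dx)
            if move > dz_cap:
                move = dz_cap
            fm = frac_mud_a[dj, di]
            mm = min(move * fm, avail_mud[dj, di])
            ms = min(move - mm, avail_sand[dj, di])
            tot = mm + ms
            if tot <= 0.0:
                continue
            z[dj, di] -= tot
            z[rj, ri] += tot
            avail_mud[dj, di] -= mm
            avail_mud[rj, ri] += mm
            avail_sand[dj, di] -= ms
            avail_sand[rj, ri] += ms
            acc_blm[dj, di] -= mm
            acc_blm[rj, ri] += mm
            acc_bl[dj, di] -= ms
            acc_bl[rj, ri] += ms
    for i in range(nx):
        for j in range(1, ny):
            dzd = z[j - 1, i] - z[j, i]
            if dzd > 0.0:
                dj, rj = j - 1, j
            else:
                dzd = -dzd
                dj, rj = j, j - 1
            if dzd <= crit_slope * dy:
                continue
            if (nonerod[dj, i] or forced[dj, i]
                    or nonerod[rj, i] or forced[rj, i]):
                continue
            move = 0.25 * (dzd - crit_slope * dy)
            if move > dz_cap:
                move = dz_cap
            fm = frac_mud_a[dj, i]
            mm = min(move * fm, avail_mud[dj, i])
            ms = min(move - mm, avail_sand[dj, i])
            tot = mm + ms
            if tot <= 0.0:
                continue
            z[dj, i] -= tot
            z[rj, i] += tot
            avail_mud[dj, i] -= mm
            avail_mud[rj, i] += mm
            avail_sand[dj, i] -= ms
            avail_sand[rj, i] += ms
            acc_blm[dj, i] -= mm
            acc_blm[rj, i] += mm
            acc_bl[dj, i] -= ms
            acc_bl[rj, i] += ms


@njit(cache=True, fastmath=True)
def simulate_burst(eta, u, v, z, forced, qsrc,
                   hv1, n1, hv2, n2,
                   m_mud, m_sand,
                   frac_mud_a, frac_sand_a, avail_mud, avail_sand, nonerod,
                   acc_dmud, acc_emud, acc_dsand, acc_esand, acc_bl, acc_blm,
                   nsteps, dt, t0, tide_amp, omega, dx, dy,
                   g, kappa, cb, cd, rho_w, h_dry, theta, gamma, diff,
                   m_ero, tau_ce, tau_cd, ws_mud, ws_sand, ks, ucr2,
                   alpha_b, alpha_t, alpha_l, rho_mud, rho_sand,
                   morfac, c_river, c_sand_river, c_mud_bc, dz_cap, dep_ceiling,
                   crit_slope, inlet_i, inlet_j0, inlet_j1,
                   diag_start, hp_thresh, sed_stride, do_morpho,
                   hp_time, tau_max, tau_sum, ledger):
    """Advance one seasonal hydrodynamic burst of ``nsteps`` steps.

    Sediment transport and bed updating run every ``sed_stride`` flow steps
    on the accumulated face volume fluxes.  Diagnostics (hydroperiod time,
    max/mean bed shear stress, tidal-prism volumes) accumulate from step
    ``diag_start``.  Returns the final model time.
    """
    ny, nx = eta.shape
    cr_c = np.empty((ny, nx))
    lam_c = np.empty((ny, nx))
    tau = np.zeros((ny, nx))
    h_prev = np.zeros((ny, nx))
    fx_acc = np.zeros((ny, nx + 1))
    fy_acc = np.zeros((ny + 1, nx))
    ndiag = 0
    acc_steps = 0

    veg_present = False
    for j in range(ny):
        for i in range(nx):
            if n1[j, i] > 0.0 or n2[j, i] > 0.0:
                veg_present = True
                break
        if veg_present:
            break

    t = t0
    for step in range(nsteps):
        t_new = t + dt
        tide = tide_amp * math.sin(omega * t_new)
        for j in range(ny):
            for i in range(nx):
                if forced[j, i]:
                    eta[j, i] = tide

        if veg_present:
            _roughness_fields(eta, z, hv1, n1, hv2, n2, cb, cd, g, kappa,
                              cr_c, lam_c)
        else:
            for j in range(ny):
                for i in range(nx):
                    cr_c[j, i] = cb
                    lam_c[j, i] = 0.0

        diag_on = step >= diag_start
        if diag_on and ndiag == 0:
            for j in range(ny):
                for i in range(nx):
                    h = eta[j, i] - z[j, i]
                    h_prev[j, i] = h if h > 0.0 else 0.0

        # Strang splitting with fused interior half-sweeps:
        # y(dt/2) x(dt) y(dt) x(dt) ... y(dt) x(dt) y(dt/2)
        if step == 0:
            _sub_step_y(eta, u, v, z, forced, qsrc, cr_c, lam_c,
                        0.5 * dt, 0.5, theta, dx, dy, g, h_dry, fy_acc, ledger)
        _sub_step_x(eta, u, v, z, forced, qsrc, cr_c, lam_c,
                    dt, 0.5, theta, dx, dy, g, h_dry, fx_acc,
                    diag_on, inlet_i, inlet_j0, inlet_j1, ledger)
        if step == nsteps - 1:
            _sub_step_y(eta, u, v, z, forced, qsrc, cr_c, lam_c,
                        0.5 * dt, 0.5, theta, dx, dy, g, h_dry, fy_acc, ledger)
        else:
            _sub_step_y(eta, u, v, z, forced, qsrc, cr_c, lam_c,
                        dt, 0.5, theta, dx, dy, g, h_dry, fy_acc, ledger)

        if gamma > 0.0:
            _smooth_velocities(u, v, gamma)

        acc_steps += 1
        if do_morpho and (acc_steps >= sed_stride or step == nsteps - 1):
            dt_sed = dt * acc_steps
            _add_river_tracers(eta, z, forced, qsrc, m_mud, m_sand,
                               c_river, c_sand_river, dt_sed, dx * dy, ledger)
            _transport_tracers(eta, u, v, z, forced, m_mud, m_sand,
                               fx_acc, fy_acc, c_mud_bc, ks, ucr2, dx, dy,
                               ledger)
            if diff > 0.0:
                _diffuse(m_mud, eta, z, forced, diff, dt_sed, dx, dy, h_dry)
                _diffuse(m_sand, eta, z, forced, diff, dt_sed, dx, dy, h_dry)
            _morpho_step(eta, u, v, z, forced, qsrc, cr_c, m_mud, m_sand,
                         frac_mud_a, frac_sand_a, avail_mud, avail_sand,
                         nonerod, acc_dmud, acc_emud, acc_dsand, acc_esand,
                         acc_bl, acc_blm, tau, dt_sed, dx, dy, g, rho_w, h_dry,
                         m_ero, tau_ce, tau_cd, ws_mud, ws_sand, ks, ucr2,
                         alpha_b, alpha_t, alpha_l, rho_mud, rho_sand,
                         morfac, c_river, c_sand_river, dz_cap, dep_ceiling,
                         crit_slope, ledger)
            fx_acc[:] = 0.0
            fy_acc[:] = 0.0
            acc_steps = 0
        elif not do_morpho:
            fx_acc[:] = 0.0
            fy_acc[:] = 0.0
            acc_steps = 0
            for j in range(ny):
                for i in range(nx):
                    h = eta[j, i] - z[j, i]
                    if h > 1e-9 and not forced[j, i]:
                        uc = 0.5 * (u[j, i] + u[j, i + 1])
                        vc = 0.5 * (v[j, i] + v[j + 1, i])
                        cr = cr_c[j, i]
                        tau[j, i] = rho_w * g * (uc * uc + vc * vc) / (cr * cr)
                    else:
                        tau[j, i] = 0.0

        if diag_on:
            ndiag += 1
            for j in range(ny):
                for i in range(nx):
                    h = eta[j, i] - z[j, i]
                    if h < 0.0:
                        h = 0.0
                    h0 = h_prev[j, i]
                    w0 = h0 > hp_thresh
                    w1 = h > hp_thresh
                    if w0 and w1:
                        hp_time[j, i] += dt
                    elif w0 and not w1:
                        hp_time[j, i] += dt * (h0 - hp_thresh) / (h0 - h)
                    elif w1 and not w0:
                        hp_time[j, i] += dt * (h - hp_thresh) / (h - h0)
                    h_prev[j, i] = h
                    if tau[j, i] > tau_max[j, i]:
                        tau_max[j, i] = tau[j, i]
                    tau_sum[j, i] += tau[j, i]
        t = t_new
    return t


# ---------------------------------------------------------------------------
# stratigraphy stack bookkeeping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _remove_species(th, fr, nlay, vol, is_mud):
    """Remove a species volume (m) from a cell's layer stack, top down.

    Returns the volume that could not be supplied (normally 0).
    """
    need = vol
    k = nlay - 1
    while need > 1e-15 and k >= 0:
        t = th[k]
        if t <= 0.0:
            k -= 1
            continue
        mud_v = t * fr[k]
        sand_v = t - mud_v
        have = mud_v if is_mud else sand_v
        take = have if have < need else need
        if take > 0.0:
            t_new = t - take
            if is_mud:
                mud_v -= take
            else:
                sand_v -= take
            th[k] = t_new
            fr[k] = mud_v / t_new if t_new > 1e-15 else 0.0
            need -= take
        k -= 1
    return need


@njit(cache=True)
def _compact(th, fr, nlay):
    """Drop empty layers; return the new layer count."""
    m = 0
    for k in range(nlay):
        if th[k] > 1e-14:
            if m != k:
                th[m] = th[k]
                fr[m] = fr[k]
            m += 1
    for k in range(m, nlay):
        th[k] = 0.0
        fr[k] = 0.0
    return m


@njit(cache=True)
def apply_season_to_stack(th3, fr3, nlay, dvol_mud, dvol_sand,
                          nominal, max_layers):
    """Apply a season's net per-cell mud/sand volume change to the stacks.

    Erosion consumes species volume top-down; deposition grows the top layer
    until it reaches the nominal thickness, then starts a new layer.  When
    the stack is full the two bottom layers merge.  Returns the total volume
    (m) that could not be eroded for lack of substrate (diagnostic; stays 0
    when availability capping works).
    """
    ny, nx, L = th3.shape
    shortfall = 0.0
    for j in range(ny):
        for i in range(nx):
            n = nlay[j, i]
            th = th3[j, i]
            fr = fr3[j, i]
            dm = dvol_mud[j, i]
            ds = dvol_sand[j, i]
            if dm == 0.0 and ds == 0.0:
                continue
            if dm < 0.0:
                shortfall += _remove_species(th, fr, n, -dm, True)
            if ds < 0.0:
                shortfall += _remove_species(th, fr, n, -ds, False)
            n = _compact(th, fr, n)
            dep_m = dm if dm > 0.0 else 0.0
            dep_s = ds if ds > 0.0 else 0.0
            dep = dep_m + dep_s
            if dep > 1e-15:
                f_new = dep_m / dep
                if n > 0 and th[n - 1] < nominal:
                    tot = th[n - 1] + dep
                    fr[n - 1] = (fr[n - 1] * th[n - 1] + f_new * dep) / tot
                    th[n - 1] = tot
                else:
                    if n == L:
                        tot = th[0] + th[1]
                        fr[0] = (fr[0] * th[0] + fr[1] * th[1]) / tot if tot > 0 else 0.0
                        th[0] = tot
                        for k in range(1, n - 1):
                            th[k] = th[k + 1]
                            fr[k] = fr[k + 1]
                        n -= 1
                        th[n] = 0.0
                        fr[n] = 0.0
                    th[n] = dep
                    fr[n] = f_new
                    n += 1
            nlay[j, i] = n
    return shortfall


@njit(cache=True)
def stack_summaries(th3, fr3, nlay, active, out_frac_mud_active,
                    out_avail_mud, out_avail_sand, out_top1m):
    """Per-cell stack summaries: active-layer mud fraction, total available
    mud/sand volumes (m) and the thickness-weighted mud fraction of the top
    1 m of substrate."""
    ny, nx, L = th3.shape
    for j in range(ny):
        for i in range(nx):
            n = nlay[j, i]
            mud_tot = 0.0
            sand_tot = 0.0
            act_rem = active
            act_mud = 0.0
            act_th = 0.0
            top_rem = 1.0
            top_mud = 0.0
            top_th = 0.0
            for k in range(n - 1, -1, -1):
                t = th3[j, i, k]
                f = fr3[j, i, k]
                mud_tot += t * f
                sand_tot += t * (1.0 - f)
                if act_rem > 0.0:
                    take = t if t < act_rem else act_rem
                    act_mud += take * f
                    act_th += take
                    act_rem -= take
                if top_rem > 0.0:
                    take = t if t < top_rem else top_rem
                    top_mud += take * f
                    top_th += take
                    top_rem -= take
            out_frac_mud_active[j, i] = act_mud / act_th if act_th > 1e-12 else 0.0
            out_avail_mud[j, i] = mud_tot
            out_avail_sand[j, i] = sand_tot
            out_top1m[j, i] = top_mud / top_th if top_th > 1e-12 else 0.0
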