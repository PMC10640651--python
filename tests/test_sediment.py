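"""Sediment fluxes, transport and stratigraphy bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mangalmorph.config import SedimentConfig
from mangalmorph.domain import build_grid
from mangalmorph.sediment import (BedState, advect_diffuse, init_bathymetry,
                                  mud_exchange, mud_fraction_top1m,
                                  sand_equilibrium_concentration,
                                  sand_transport, slope_correction, update_bed)


def single_cell_bed(layers, non_erodible=False):
    """BedState with one cell and a prescribed (bottom-up) layer stack."""
    L = 8
    th = np.zeros((1, 1, L))
    fr = np.zeros((1, 1, L))
    for k, (t, f) in enumerate(layers):
        th[0, 0, k] = t
        fr[0, 0, k] = f
    nlay = np.array([[len(layers)]], dtype=np.int32)
    z = np.array([[sum(t for t, _ in layers)]]) - 10.0
    z_floor = z - th.sum(axis=2)
    return BedState(z=z, th=th, fr=fr, nlay=nlay,
                    non_erodible=np.array([[non_erodible]]), z_floor=z_floor)


class TestMudExchange:
    def test_threshold_behaviour(self, sed_cfg):
        ero, _ = mud_exchange(sed_cfg.tau_ce, 0.0, sed_cfg)
        assert ero == 0.0
        ero2, _ = mud_exchange(2 * sed_cfg.tau_ce, 0.0, sed_cfg)
        assert ero2 == pytest.approx(sed_cfg.m_erosion)

    def test_still_water_settling(self, sed_cfg):
        _, dep = mud_exchange(0.0, 0.02, sed_cfg)
        assert dep == pytest.approx(sed_cfg.ws_mud * 0.02)

    def test_surface_mud_availability_scales_erosion(self, sed_cfg):
        e_full, _ = mud_exchange(0.6, 0.0, sed_cfg, surface_mud_fraction=1.0)
        e_half, _ = mud_exchange(0.6, 0.0, sed_cfg, surface_mud_fraction=0.5)
        assert e_half == pytest.approx(0.5 * e_full)


class TestSandTransport:
    def test_no_motion_below_critical_speed(self, sed_cfg):
        src, (qx, qy) = sand_transport(0.2, 0.0, 0.0, sed_cfg)
        assert src == 0.0 and qx == 0.0 and qy == 0.0
        assert sand_equilibrium_concentration(0.29, sed_cfg) == 0.0

    def test_capacity_strictly_increasing_with_speed(self, sed_cfg):
        speeds = [0.4, 0.6, 0.9, 1.4]
        caps = [sand_equilibrium_concentration(s, sed_cfg) for s in speeds]
        assert all(b > a for a, b in zip(caps, caps[1:]))
        mags = [np.hypot(*sand_transport(s, 0.0, 0.0, sed_cfg)[1]) for s in speeds]
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_relaxation_toward_equilibrium(self, sed_cfg):
        ceq = sand_equilibrium_concentration(1.0, sed_cfg)
        src_at_eq, _ = sand_transport(1.0, 0.0, ceq, sed_cfg)
        assert src_at_eq == pytest.approx(0.0, abs=1e-15)
        src_clear, _ = sand_transport(1.0, 0.0, 0.0, sed_cfg)
        assert src_clear > 0
        src_loaded, _ = sand_transport(1.0, 0.0, 2 * ceq, sed_cfg)
        assert src_loaded < 0


class TestSlopeCorrection:
    def setup_method(self):
        ny, nx = 5, 5
        self.qbx = np.zeros((ny, nx))
        self.qby = np.zeros((ny, nx))
        self.qbx[2, 2] = 1e-4  # along-x transport at the centre cell

    def test_flat_bed_unchanged(self, sed_cfg):
        z = np.zeros((5, 5))
        ox, oy = slope_correction(self.qbx, self.qby, z, 60.0, 60.0, sed_cfg)
        assert ox[2, 2] == pytest.approx(1e-4)
        assert oy[2, 2] == 0.0

    def test_lateral_slope_drives_downslope_transverse_flux(self, sed_cfg):
        z = np.tile(np.arange(5)[:, None] * 0.5, (1, 5))  # rises with y
        _, oy = slope_correction(self.qbx, self.qby, z, 60.0, 60.0, sed_cfg)
        assert oy[2, 2] < 0  # flux deflected toward lower ground

    def test_reversing_slope_reverses_transverse_component(self, sed_cfg):
        z = np.tile(np.arange(5)[:, None] * 0.5, (1, 5))
        _, oy1 = slope_correction(self.qbx, self.qby, z, 60.0, 60.0, sed_cfg)
        _, oy2 = slope_correction(self.qbx, self.qby, -z, 60.0, 60.0, sed_cfg)
        assert oy2[2, 2] == pytest.approx(-oy1[2, 2])


class TestAdvectDiffuse:
    def test_quiescent_field_unchanged(self):
        m = np.random.default_rng(0).random((4, 6))
        h = np.ones((4, 6))
        out = advect_diffuse(m, np.zeros((4, 7)), np.zeros((5, 6)), h,
                             dt=100.0, dx=50.0, dy=50.0)
        assert out == pytest.approx(m)

    def test_closed_domain_mass_conserved(self):
        rng = np.random.default_rng(1)
        ny, nx = 6, 12
        m = rng.random((ny, nx))
        h = np.ones((ny, nx))
        u = np.zeros((ny, nx + 1))
        u[:, 1:-1] = 0.1 * rng.uniform(-1, 1, (ny, nx - 1))
        v = np.zeros((ny + 1, nx))
        v[1:-1, :] = 0.1 * rng.uniform(-1, 1, (ny - 1, nx))
        out = m.copy()
        for _ in range(20):
            out = advect_diffuse(out, u, v, h, dt=100.0, dx=50.0, dy=50.0,
                                 diffusivity=1.0)
        assert out.sum() == pytest.approx(m.sum(), rel=1e-8)
        assert out.min() >= 0

    def test_pulse_advects_at_flow_speed(self):
        """Method-of-characteristics oracle: centroid moves at u*t."""
        ny, nx = 3, 60
        m = np.zeros((ny, nx))
        m[1, 5] = 1.0
        h = np.ones((ny, nx))
        speed = 0.4
        u = np.full((ny, nx + 1), speed)
        v = np.zeros((ny + 1, nx))
        dt, dx, steps = 50.0, 50.0, 40
        out = m.copy()
        for _ in range(steps):
            out = advect_diffuse(out, u, v, h, dt=dt, dx=dx, dy=dx)
        x = np.arange(nx) * dx
        centroid = (out[1] * x).sum() / out[1].sum()
        expected = 5 * dx + speed * dt * steps
        assert centroid == pytest.approx(expected, abs=dx)

    def test_cfl_violation_rejected(self):
        with pytest.raises(ValueError):
            advect_diffuse(np.zeros((3, 5)), np.full((3, 6), 2.0),
                           np.zeros((4, 5)), np.ones((3, 5)),
                           dt=100.0, dx=50.0, dy=50.0)


class TestUpdateBed:
    def test_pure_mud_deposition_bookkeeping(self, sed_cfg):
        bed = single_cell_bed([(2.0, 0.0)])
        z0 = bed.z[0, 0]
        flux = 1e-4  # kg/m2/s deposition
        update_bed(bed, flux, 0.0, 0.0, 0.0, morfac=90.0, dt=300.0, cfg=sed_cfg)
        dz = 90.0 * 300.0 * flux / sed_cfg.rho_dry_mud
        assert bed.z[0, 0] - z0 == pytest.approx(dz)
        top = bed.nlay[0, 0] - 1
        assert bed.fr[0, 0, top] == pytest.approx(1.0)

    def test_zero_flux_identity(self, sed_cfg):
        bed = single_cell_bed([(2.0, 0.3)])
        z0, th0 = bed.z.copy(), bed.th.copy()
        update_bed(bed, 0.0, 0.0, 0.0, 0.0, morfac=90.0, dt=300.0, cfg=sed_cfg)
        assert bed.z == pytest.approx(z0)
        assert bed.th == pytest.approx(th0)

    def test_erosion_beyond_stack_rejected(self, sed_cfg):
        bed = single_cell_bed([(0.01, 1.0)])
        with pytest.raises(ValueError):
            update_bed(bed, 0.0, 1.0, 0.0, 0.0, morfac=90.0, dt=3600.0,
                       cfg=sed_cfg)

    def test_non_erodible_cell_never_lowers(self, sed_cfg):
        bed = single_cell_bed([(2.0, 0.5)], non_erodible=True)
        z0 = bed.z[0, 0]
        update_bed(bed, 0.0, 1e-3, 0.0, 1e-3, morfac=90.0, dt=300.0,
                   cfg=sed_cfg)
        assert bed.z[0, 0] >= z0


class TestTopMetreMudFraction:
    @pytest.mark.parametrize("layers,expected", [
        ([(1.0, 0.4)], 0.4),
        ([(0.5, 0.0), (0.5, 1.0)], 0.5),        # top layer pure mud
        ([(0.9, 0.1), (0.2, 1.0)], 0.28),       # truncated stack, hand value
    ])
    def test_weighted_mean_of_top_metre(self, layers, expected):
        bed = single_cell_bed(layers)
        assert mud_fraction_top1m(bed)[0, 0] == pytest.approx(expected)

    def test_deep_stack_ignores_buried_mud(self):
        bed = single_cell_bed([(5.0, 1.0), (1.5, 0.0)])
        assert mud_fraction_top1m(bed)[0, 0] == pytest.approx(0.0)


class TestStratigraphyInvariants:
    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-0.05, 0.1), st.floats(0.0, 0.1)),
                    min_size=1, max_size=25))
    def test_species_volumes_conserved_and_fractions_bounded(self, seq):
        """Random deposit/erode sequences keep the stack consistent: species
        volumes match the applied net changes and every layer fraction stays
        inside [0, 1]."""
        cfg = SedimentConfig(max_layers=48)
        g = build_grid(60.0)
        bed = init_bathymetry(g, sed_cfg=cfg)
        j, i = g.ny // 2, g.ix_barrier + 5
        mud0, sand0 = (a[j, i] for a in bed.species_volumes())
        exp_mud, exp_sand = mud0, sand0
        for dm, ds in seq:
            dmud = np.zeros((g.ny, g.nx))
            dsand = np.zeros((g.ny, g.nx))
            cur_mud = (bed.th[j, i] * bed.fr[j, i]).sum()
            dm = max(dm, -cur_mud)  # never request more than available
            dmud[j, i] = dm
            dsand[j, i] = ds
            bed.apply_season(dmud, dsand, cfg)
            exp_mud += dm
            exp_sand += ds
        mud1, sand1 = (a[j, i] for a in bed.species_volumes())
        assert mud1 == pytest.approx(exp_mud, abs=1e-9)
        assert sand1 == pytest.approx(exp_sand, abs=1e-9)
        n = bed.nlay[j, i]
        assert (bed.fr[j, i, :n] >= -1e-12).all()
        assert (bed.fr[j, i, :n] <= 1 + 1e-12).all()
        assert bed.z[j, i] == pytest.approx(
            bed.z_floor[j, i] + bed.th[j, i].sum())
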