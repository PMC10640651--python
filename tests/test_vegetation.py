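"""Mangrove life cycle: allometry, growth, colonization, mortality, removal."""

import numpy as np
import pytest

from mangalmorph.config import VegetationConfig
from mangalmorph.vegetation import (VegetationState, apply_mortality,
                                    attempt_colonization, competition,
                                    compute_stress, fitness, grow_cohorts,
                                    pneumatophore_density, remove_mangroves,
                                    stem_biomass, thinning_target,
                                    tick_root_persistence, to_roughness_summary,
                                    tree_height)

CELL = 3600.0  # 60 m cells


@pytest.fixture
def veg():
    return VegetationState.empty(4, 5)


def colonize_all(veg, cfg, hp=0.3, tau=0.1):
    ny, nx = veg.stems.shape
    attempt_colonization(veg, np.full((ny, nx), hp), np.full((ny, nx), tau),
                         np.ones((ny, nx), bool), CELL, cfg)


class TestAllometry:
    def test_seedling_intercept(self, veg_cfg):
        assert tree_height(0.0, veg_cfg) == pytest.approx(137.0)

    def test_height_nondecreasing_up_to_vertex(self, veg_cfg):
        d = np.linspace(0, veg_cfg.b2 / (2 * veg_cfg.b3), 50)
        h = tree_height(d, veg_cfg)
        assert (np.diff(h) >= 0).all()

    def test_maximum_size_consistency(self, veg_cfg):
        assert tree_height(veg_cfg.d_max, veg_cfg) == pytest.approx(
            veg_cfg.h_max, rel=1e-6)


class TestGrowth:
    def test_no_growth_at_size_ceiling(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        veg.d_cm[:] = np.where(veg.mask, veg_cfg.d_max, 0.0)
        f = np.ones(veg.stems.shape)
        grow_cohorts(veg, f, f, 0.25, veg_cfg)
        assert veg.d_cm[veg.mask] == pytest.approx(veg_cfg.d_max)

    def test_zero_stress_product_freezes_diameter(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        d0 = veg.d_cm.copy()
        zero = np.zeros(veg.stems.shape)
        grow_cohorts(veg, zero, np.ones_like(zero), 0.25, veg_cfg)
        assert veg.d_cm == pytest.approx(d0)

    def test_single_optimal_season_matches_scalar_oracle(self, veg_cfg, veg):
        """One explicit-Euler season against an independent scalar evaluation
        of the growth law at the seedling size."""
        colonize_all(veg, veg_cfg)
        one = np.ones(veg.stems.shape)
        grow_cohorts(veg, one, one, 0.25, veg_cfg)
        d = 0.5
        h = 137.0 + veg_cfg.b2 * d - veg_cfg.b3 * d**2
        rate = (veg_cfg.growth_g * d
                * (1.0 - d * h / (veg_cfg.d_max * veg_cfg.h_max))
                / (274.0 + 3 * veg_cfg.b2 * d - 4 * veg_cfg.b3 * d**2))
        assert veg.d_cm[veg.mask][0] == pytest.approx(0.5 + 0.25 * rate,
                                                      rel=1e-12)

    def test_diameter_saturates_monotonically_under_optimal_conditions(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        one = np.ones(veg.stems.shape)
        prev = veg.d_cm[0, 0]
        for _ in range(400):
            grow_cohorts(veg, one, one, 0.25, veg_cfg)
            cur = veg.d_cm[0, 0]
            assert cur >= prev - 1e-12
            assert cur <= veg_cfg.d_max + 1e-9
            prev = cur
        assert prev > 0.8 * veg_cfg.d_max  # approaches the ceiling


class TestColonization:
    def test_eligible_cell_gets_reference_density(self, veg_cfg, veg):
        hp = np.full(veg.stems.shape, 0.3)
        tau = np.full(veg.stems.shape, 0.1)
        new = attempt_colonization(veg, hp, tau,
                                   np.ones(veg.stems.shape, bool), CELL, veg_cfg)
        assert new.all()
        # 3000 individuals/ha on a 3600 m2 cell
        assert veg.stems[0, 0] == pytest.approx(3000.0 / 1e4 * CELL)
        assert veg.d_cm[0, 0] == veg_cfg.seedling_diameter

    @pytest.mark.parametrize("hp,tau,ok", [
        (0.3, 0.1, True),
        (0.6, 0.1, False),    # outside the hydroperiod window
        (0.3, 0.25, False),   # bed shear stress above the settling limit
        (0.0, 0.1, False),    # never inundated
        (0.02, 0.1, False),   # too dry for viable growth (f*C <= 0.5)
    ])
    def test_settlement_gates(self, veg_cfg, veg, hp, tau, ok):
        shape = veg.stems.shape
        new = attempt_colonization(veg, np.full(shape, hp), np.full(shape, tau),
                                   np.ones(shape, bool), CELL, veg_cfg)
        assert new.any() == ok

    def test_vegetated_cells_not_reseeded(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        veg.d_cm[:] = np.where(veg.mask, 5.0, 0.0)
        new = attempt_colonization(veg, np.full(veg.stems.shape, 0.3),
                                   np.full(veg.stems.shape, 0.1),
                                   np.ones(veg.stems.shape, bool), CELL, veg_cfg)
        assert not new.any()
        assert veg.d_cm.max() == 5.0


class TestStress:
    def test_bounds_and_empty_cell_optimum(self, veg_cfg, veg):
        hp = np.full(veg.stems.shape, 0.3)
        f, c = compute_stress(veg, hp, CELL, veg_cfg)
        assert f.max() <= 1.0 and c.max() == 1.0
        assert f[0, 0] == 1.0

    def test_dry_end_minimum_and_wet_cutoff(self, veg_cfg):
        assert fitness(0.0, veg_cfg) == 0.0
        assert fitness(0.6, veg_cfg) == 0.0
        assert 0 < fitness(0.05, veg_cfg) < 1

    def test_competition_decays_with_biomass(self, veg_cfg):
        assert competition(0.0, veg_cfg) == 1.0
        assert competition(1e9, veg_cfg) == pytest.approx(0.0, abs=1e-6)
        b = np.linspace(0, 100, 20)
        assert (np.diff(competition(b, veg_cfg)) < 0).all()


class TestMortality:
    def _year(self, veg, cfg, fc):
        shape = veg.stems.shape
        f = np.full(shape, fc)
        apply_mortality(veg, f, np.ones(shape), CELL, cfg)

    def test_five_consecutive_suppressed_years_trigger_thinning(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        veg.d_cm[:] = np.where(veg.mask, 10.0, 0.0)
        s0 = veg.stems[0, 0]
        for _ in range(4):
            self._year(veg, veg_cfg, 0.4)
            assert veg.stems[0, 0] == s0  # not yet
        self._year(veg, veg_cfg, 0.4)
        assert veg.stems[0, 0] < s0

    def test_broken_streak_resets_the_counter(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        veg.d_cm[:] = np.where(veg.mask, 10.0, 0.0)
        s0 = veg.stems[0, 0]
        for fc in (0.4, 0.4, 0.6, 0.4, 0.4):
            self._year(veg, veg_cfg, fc)
        assert veg.stems[0, 0] == s0
        for fc in (0.4, 0.4, 0.4):
            self._year(veg, veg_cfg, fc)
        assert veg.stems[0, 0] < s0

    def test_thinning_matches_stem_by_stem_brute_force(self, veg_cfg):
        """Removing stems one at a time until f*C recovers gives the same
        count as the closed-form target."""
        f, d = 0.8, 12.0
        per_stem = stem_biomass(d, veg_cfg)
        stems = 3000.0
        while stems > 0:
            c = competition(stems * per_stem / CELL, veg_cfg)
            if f * c >= veg_cfg.viability:
                break
            stems -= 1
        assert thinning_target(f, d, CELL, veg_cfg) == pytest.approx(stems, abs=1)

    def test_hopeless_fitness_clears_the_cell(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        for _ in range(veg_cfg.suppression_years):
            self._year(veg, veg_cfg, 0.0)
        assert not veg.mask.any()


class TestRemoval:
    def test_full_removal_clears_everything_at_once(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        remove_mangroves(veg, 1.0, CELL, veg_cfg)
        assert not veg.mask.any()

    def test_partial_removal_fraction(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        n0 = int(veg.mask.sum())
        remove_mangroves(veg, 0.25, CELL, veg_cfg)
        assert abs(int(veg.mask.sum()) - round(0.75 * n0)) <= 1

    def test_seaward_first_selection(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        remove_mangroves(veg, 0.5, CELL, veg_cfg)
        # cleared cells have strictly smaller (more seaward) x than kept ones
        cleared_x = np.nonzero(~veg.mask)[1]
        kept_x = np.nonzero(veg.mask)[1]
        assert cleared_x.max() <= kept_x.min()

    def test_invalid_fraction_rejected(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        with pytest.raises(ValueError):
            remove_mangroves(veg, 0.0, CELL, veg_cfg)
        with pytest.raises(ValueError):
            remove_mangroves(veg, 1.5, CELL, veg_cfg)

    def test_root_persistence_keeps_pneumatophores_then_drops_them(self, veg_cfg, veg):
        colonize_all(veg, veg_cfg)
        veg.d_cm[:] = np.where(veg.mask, 10.0, 0.0)
        pn_before = pneumatophore_density(veg, CELL, veg_cfg)[0, 0]
        remove_mangroves(veg, 1.0, CELL, veg_cfg, root_persistence_years=2.0)
        hv1, n1, hv2, n2 = to_roughness_summary(veg, CELL, veg_cfg)
        assert n2.max() == 0.0                       # stems gone immediately
        assert n1[0, 0] == pytest.approx(pn_before * veg_cfg.pneu_diameter)
        tick_root_persistence(veg)
        assert pneumatophore_density(veg, CELL, veg_cfg).max() > 0
        tick_root_persistence(veg)
        assert pneumatophore_density(veg, CELL, veg_cfg).max() == 0.0


class TestRoughnessSummary:
    def test_density_is_count_density_times_diameter(self, veg_cfg):
        veg = VegetationState.empty(1, 1)
        veg.stems[0, 0] = 100.0
        veg.d_cm[0, 0] = 5.0  # 0.05 m
        _, _, hv2, n2 = to_roughness_summary(veg, 225.0, veg_cfg)
        assert n2[0, 0] == pytest.approx(100.0 / 225.0 * 0.05)
        assert hv2[0, 0] == pytest.approx(tree_height(5.0, veg_cfg) / 100.0)

    def test_linearity_in_stem_count(self, veg_cfg):
        veg = VegetationState.empty(1, 1)
        veg.stems[0, 0] = 100.0
        veg.d_cm[0, 0] = 5.0
        n_single = to_roughness_summary(veg, 225.0, veg_cfg)[3][0, 0]
        veg.stems[0, 0] = 200.0
        assert to_roughness_summary(veg, 225.0, veg_cfg)[3][0, 0] == \
            pytest.approx(2 * n_single)

    def test_empty_cell_has_zero_density(self, veg_cfg):
        veg = VegetationState.empty(2, 2)
        for arr in to_roughness_summary(veg, CELL, veg_cfg)[1::2]:
            assert arr.max() == 0.0
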