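"""Landscape metrics on constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from mangalmorph.config import SedimentConfig
from mangalmorph.metrics import (ChannelClassification, accommodation_space,
                                 classify_channels, mangrove_coverage,
                                 muddy_region_fraction, rate_by_class,
                                 read_estuary_table, relative_area_amsl,
                                 sediment_yield_and_prism, sedimentation_rate)

HW = 0.75


class TestAccommodationSpace:
    def test_uniform_bed(self):
        z = np.full((4, 5), -1.0)
        mask = np.ones((4, 5), bool)
        assert accommodation_space(z, mask, HW, 3600.0) == pytest.approx(
            (HW + 1.0) * 20 * 3600.0)

    def test_everything_above_high_water(self):
        z = np.full((3, 3), 2.0)
        assert accommodation_space(z, np.ones((3, 3), bool), HW, 3600.0) == 0.0

    def test_two_cell_hand_sum(self):
        z = np.array([[-1.5, 1.0]])
        mask = np.ones((1, 2), bool)
        assert accommodation_space(z, mask, HW, 3600.0) == pytest.approx(8100.0)

    def test_depends_only_on_hypsometry(self, rng):
        z = rng.uniform(-2, 1, (6, 8))
        mask = np.ones((6, 8), bool)
        a1 = accommodation_space(z, mask, HW, 3600.0)
        shuffled = rng.permutation(z.ravel()).reshape(z.shape)
        assert accommodation_space(shuffled, mask, HW, 3600.0) == pytest.approx(a1)


class TestMuddyRegion:
    def test_threshold_count(self):
        f = np.array([[0.2, 0.4, 0.31]])
        mask = np.ones((1, 3), bool)
        assert muddy_region_fraction(f, mask) == pytest.approx(2 / 3)

    def test_all_sand_basin(self):
        assert muddy_region_fraction(np.zeros((3, 3)), np.ones((3, 3), bool)) == 0.0

    def test_exact_threshold_excluded(self):
        f = np.full((1, 4), 0.30)
        assert muddy_region_fraction(f, np.ones((1, 4), bool)) == 0.0


class TestCoverageAndIntertidalArea:
    def test_coverage_counting(self):
        veg = np.zeros((10, 10), bool)
        veg[:3, :9] = True
        assert mangrove_coverage(veg, np.ones((10, 10), bool)) == pytest.approx(0.27)
        assert mangrove_coverage(np.zeros((2, 2), bool), np.ones((2, 2), bool)) == 0.0

    def test_amsl_counting(self):
        z = np.array([[-1.5] * 7 + [0.3, 0.4, 0.5]])
        mask = np.ones((1, 10), bool)
        assert relative_area_amsl(z, mask, HW) == pytest.approx(0.3)

    def test_amsl_initial_basin_is_zero(self):
        z = np.full((5, 5), -1.5)
        assert relative_area_amsl(z, np.ones((5, 5), bool), HW) == 0.0

    def test_amsl_supratidal_limit(self):
        # one tidal cell above MSL, everything else supratidal
        z = np.full((1, 10), 2.0)
        z[0, 0] = 0.3
        assert relative_area_amsl(z, np.ones((1, 10), bool), HW) == 1.0


class TestChannelClassification:
    @pytest.fixture
    def incised_platform(self):
        """Flat platform at 0 m with a straight channel incised 1 m deep."""
        z = np.zeros((21, 40))
        z[10, :] = -1.0
        return z

    def test_mask_recovers_synthetic_incision(self, incised_platform):
        mask = np.ones(incised_platform.shape, bool)
        cc = classify_channels(incised_platform, mask, dx=60.0)
        assert cc.channel[10, 5:35].all()
        assert not cc.channel[5, :].any()

    def test_distance_classes(self, incised_platform):
        mask = np.ones(incised_platform.shape, bool)
        cc = classify_channels(incised_platform, mask, dx=60.0)
        assert cc.distance[10, 20] == 0.0
        assert cc.distance[11, 20] == pytest.approx(60.0)
        assert cc.near[11, 20]
        # five cells away at 60 m -> 300 m, inside the 300-400 m class
        assert cc.distance[15, 20] == pytest.approx(300.0)
        assert cc.far[15, 20]
        assert not cc.near[15, 20]

    def test_flat_platform_has_no_channels(self):
        z = np.zeros((15, 15))
        cc = classify_channels(z, np.ones((15, 15), bool), dx=60.0)
        assert not cc.channel.any()

    def test_subtidal_override_needs_relief_support(self):
        # a subtidal incision too shallow for the relief rule alone is still
        # picked up, but a uniformly subtidal platform is not channelized
        z = np.full((15, 15), -0.6)
        z[7, :] = -0.85   # 0.25 m relief, below mean low water
        cc = classify_channels(z, np.ones((15, 15), bool), dx=60.0)
        assert cc.channel[7, 3:12].all()
        flat = np.full((15, 15), -1.2)
        cc2 = classify_channels(flat, np.ones((15, 15), bool), dx=60.0)
        assert not cc2.channel.any()


class TestSedimentationRate:
    def test_hand_values(self):
        assert sedimentation_rate(0.0, 0.05, 50.0) == pytest.approx(1.0)
        assert sedimentation_rate(0.0, -0.1, 100.0) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            sedimentation_rate(0.0, 0.1, 0.0)

    def test_class_means_on_two_class_fixture(self):
        rates = np.zeros((4, 4))
        channel = np.zeros((4, 4), bool)
        near = np.zeros((4, 4), bool)
        far = np.zeros((4, 4), bool)
        channel[0, :2] = True
        near[1, :] = True
        far[2, :2] = True
        rates[1, :] = [1.0, 2.0, 3.0, 4.0]
        rates[2, :2] = [10.0, 20.0]
        cc = ChannelClassification(channel, np.zeros((4, 4)), near, far)
        means = rate_by_class(rates, cc)
        assert means["near"] == pytest.approx(2.5)
        assert means["far"] == pytest.approx(15.0)
        assert means["channel"] == pytest.approx(0.0)


class TestSedimentYield:
    def test_three_river_annual_load(self):
        # 3 rivers x 18 m3/s x 15 mg/L over a Julian year
        sy = 3 * 18.0 * 0.015 * 86400 * 365.25
        assert sy == pytest.approx(2.556e7, rel=1e-3)
        out = sediment_yield_and_prism(sy, 1.33e7)
        assert out["SY_m3_yr"] == pytest.approx(sy / 500.0)
        assert out["SY_TP"] == pytest.approx(sy / 500.0 / 1.33e7)

    def test_zero_concentration_and_linearity(self):
        assert sediment_yield_and_prism(0.0, 1e7)["SY_TP"] == 0.0
        a = sediment_yield_and_prism(1e6, 1e7)["SY_TP"]
        b = sediment_yield_and_prism(3e6, 1e7)["SY_TP"]
        assert b == pytest.approx(3 * a)


class TestEstuaryTable:
    def test_reader_roundtrip(self, tmp_path):
        df = pd.DataFrame({
            "estuary": ["Whangapoua-like", "Wharekawa-like"],
            "SY_m3_yr": [1.2e4, 3.4e4],
            "TP_m3": [1.1e7, 6.0e6],
            "A_MSL_A_tot": [0.35, 0.55],
        })
        p = tmp_path / "estuaries.csv"
        df.to_csv(p, index=False)
        out = read_estuary_table(p)
        assert out["SY_TP"].iloc[0] == pytest.approx(1.2e4 / 1.1e7)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"estuary": ["x"]}).to_csv(p, index=False)
        with pytest.raises(ValueError):
            read_estuary_table(p)
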