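import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nearroad import emissions
from nearroad.emissions import (bpr_speed, adjust_total_volume, class_volumes,
                                nearest_speed_bin, season_of,
                                segment_emission_rate, fleet_rate_per_vehicle)
from nearroad.synth import ScenarioConfig, generate_emission_table, generate_traffic


@pytest.fixture(scope="module")
def factors():
    _, f = generate_traffic(ScenarioConfig(seed=7))
    return f


@pytest.fixture(scope="module")
def ef_table():
    return generate_emission_table(ScenarioConfig(seed=7))


class TestBprSpeed:
    def test_freeway_at_capacity(self):
        # the fitted freeway coefficients drop 60 mph to 53.4 at capacity
        assert round(bpr_speed(60, 2000, 2000, 0.1226, 4.688), 1) == 53.4

    def test_arterial_at_capacity(self):
        assert bpr_speed(35, 825, 825, 1.00, 4.688) == pytest.approx(17.5)

    def test_zero_volume_gives_free_flow(self):
        assert bpr_speed(60, 0, 2000, 0.1226, 4.688) == 60.0

    def test_half_capacity_hand_value(self):
        assert bpr_speed(60, 1000, 2000, 0.1226, 4.688) == pytest.approx(
            59.71597772753599, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bpr_speed(60, -1, 2000, 0.1226, 4.688)
        with pytest.raises(ValueError):
            bpr_speed(60, 100, 0, 0.1226, 4.688)

    @given(v=st.lists(st.floats(0, 12000), min_size=2, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_nonincreasing_and_bounded(self, v):
        v = np.sort(np.array(v))
        s = bpr_speed(60, v, 12000, 0.1226, 4.688)
        assert np.all(np.diff(s) <= 1e-9)
        assert np.all(s <= 60.0)

    def test_below_90pct_capacity_speed_drop_under_5mph(self):
        # below 90% of capacity the case-study coefficients never shave
        # more than 5 mph off free flow
        v = np.linspace(0, 0.9 * 12000, 200)
        s = bpr_speed(60, v, 12000, 0.1226, 4.688)
        assert np.all(60 - s < 5.0)


class TestDayTypeAdjustment:
    def test_weekday_identity(self, factors):
        for h in range(24):
            assert adjust_total_volume(1000.0, "weekday", h, factors) == 1000.0

    def test_scaling(self, factors):
        f1 = factors.f1.loc[8, "sunday"]
        assert adjust_total_volume(1000.0, "sunday", 8, factors) == \
            pytest.approx(1000.0 * f1)

    def test_zero_volume(self, factors):
        assert adjust_total_volume(0.0, "saturday", 1, factors) == 0.0


class TestClassVolumes:
    def test_weekday_equals_mix_times_volume(self, factors):
        cv = class_volumes(1000.0, factors, "weekday", 8, "freeway")
        f2 = factors.mix_fractions("freeway", 8)
        pd.testing.assert_series_equal(cv, 1000.0 * f2, check_names=False)

    def test_two_class_hand_normalisation(self):
        # V=100, F2=(0.8, 0.2), F3=(1.0, 0.5): V* = (80, 10) -> renormalised
        # to (88.889, 11.111); oracle is hand arithmetic
        f1 = pd.DataFrame({"weekday": np.ones(24), "sunday": np.full(24, 0.7)},
                          index=range(24))
        mix = pd.DataFrame(
            {("freeway", "LDV"): np.full(24, 0.8),
             ("freeway", "HDDV"): np.full(24, 0.2)}, index=range(24))
        mix.columns = pd.MultiIndex.from_tuples(mix.columns)
        f3 = pd.DataFrame(
            {("sunday", "light"): np.ones(24),
             ("sunday", "heavy"): np.full(24, 0.5)}, index=range(24))
        f3.columns = pd.MultiIndex.from_tuples(f3.columns)
        fac = emissions.DayTypeFactors(f1=f1, f3=f3, mix=mix)
        cv = class_volumes(100.0, fac, "sunday", 0, "freeway")
        assert cv["LDV"] == pytest.approx(800.0 / 9.0)
        assert cv["HDDV"] == pytest.approx(100.0 / 9.0)

    @pytest.mark.parametrize("day_type, hour", [
        ("saturday", 3), ("sunday", 8), ("holiday", 17), ("weekday", 12)])
    def test_always_sums_to_total(self, factors, day_type, hour):
        cv = class_volumes(5432.1, factors, day_type, hour, "arterial")
        assert cv.sum() == pytest.approx(5432.1)


class TestSeasonAndLookup:
    @pytest.mark.parametrize("month, season", [
        (1, "winter"), (2, "winter"), (12, "winter"),
        (3, "springfall"), (5, "springfall"), (9, "springfall"), (11, "springfall"),
        (6, "summer"), (7, "summer"), (8, "summer")])
    def test_season_of(self, month, season):
        assert season_of(month) == season

    def test_season_rejects_bad_month(self):
        with pytest.raises(ValueError):
            season_of(13)

    @pytest.mark.parametrize("speed, bin_", [
        (30.0, 30), (53.4, 55), (70.0, 65), (2.0, 5), (52.5, 55), (47.5, 50)])
    def test_nearest_bin(self, speed, bin_):
        assert nearest_speed_bin(speed) == bin_

    def test_unknown_keys_raise(self, ef_table):
        with pytest.raises(KeyError):
            ef_table.lookup("O3", "winter", "LDV", 30)
        with pytest.raises(KeyError):
            ef_table.lookup("CO", "winter", "TRAIN", 30)

    def test_incomplete_grid_rejected(self, ef_table):
        broken = ef_table.frame[ef_table.frame.speed_mph != 35]
        with pytest.raises(ValueError, match="incomplete"):
            emissions.EmissionFactorTable(broken)


class TestSegmentEmissionRate:
    def single_class_table(self, q):
        rows = [("CO", s, "LDV", int(b), q)
                for s in emissions.SEASONS for b in emissions.SPEED_BINS]
        return emissions.EmissionFactorTable(pd.DataFrame(
            rows, columns=["pollutant", "season", "class", "speed_mph", "g_per_mi"]))

    def test_unit_conversion_only(self):
        # one class, V=1000 veh/h, q=1 g/mi -> Q = 625 g/h/km
        table = self.single_class_table(1.0)
        q, e = segment_emission_rate({"LDV": 1000.0}, table, 30, "CO", "winter")
        assert q == pytest.approx(625.0)
        assert e == pytest.approx(0.625)

    def test_zero_volume(self):
        table = self.single_class_table(1.0)
        q, e = segment_emission_rate({"LDV": 0.0}, table, 30, "CO", "winter")
        assert q == 0.0 and e == 0.0

    def test_two_class_hand_value(self):
        # V=10000, mix (0.9, 0.1), q=(10, 2) g/mi -> Q = 57500 g/h/km
        rows = []
        for s in emissions.SEASONS:
            for b in emissions.SPEED_BINS:
                rows += [("CO", s, "LDV", int(b), 10.0),
                         ("CO", s, "HDDV", int(b), 2.0)]
        table = emissions.EmissionFactorTable(pd.DataFrame(
            rows, columns=["pollutant", "season", "class", "speed_mph", "g_per_mi"]))
        q, e = segment_emission_rate(
            {"LDV": 9000.0, "HDDV": 1000.0}, table, 55, "CO", "summer")
        assert q == pytest.approx(57500.0)
        assert e == pytest.approx(5.75)

    def test_strict_units_flag(self):
        table = self.single_class_table(1.0)
        q, _ = segment_emission_rate({"LDV": 1000.0}, table, 30, "CO", "winter",
                                     strict_units=True)
        assert q == pytest.approx(1000.0 / 1.609344)

    @given(scale=st.floats(0.1, 50))
    @settings(max_examples=50, derandomize=True)
    def test_homogeneous_in_volume(self, scale, ef_table):
        mix = {"LDV": 800.0, "HDDV": 200.0}
        q1, e1 = segment_emission_rate(mix, ef_table, 40, "CO", "winter")
        q2, e2 = segment_emission_rate(
            {k: v * scale for k, v in mix.items()}, ef_table, 40, "CO", "winter")
        assert q2 == pytest.approx(scale * q1)
        assert e2 == pytest.approx(e1)

    def test_pm25_rate_invariant_to_speed(self, ef_table):
        mix = {"LDV": 700.0, "LDT1": 100.0, "HDDV": 200.0}
        rates = [fleet_rate_per_vehicle(mix, ef_table, s, "PM2.5", "summer")
                 for s in (7.0, 23.0, 41.0, 64.0)]
        assert np.ptp(rates) == pytest.approx(0.0, abs=1e-15)

    def test_empty_class_set_raises(self, ef_table):
        with pytest.raises(ValueError):
            fleet_rate_per_vehicle({}, ef_table, 30, "CO", "winter")
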