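"""Data-selection rules: clear-sky screening, flags, agreement, closure."""

import numpy as np
import pandas as pd
import pytest

import ecoforcing as ef
from ecoforcing import qc_filters as qc


class TestClearSkyIndex:
    def test_simple_ratio(self):
        assert qc.clear_sky_index(750.0, 1000.0, 1.0) == pytest.approx(0.75)

    def test_low_sun_guard(self):
        assert np.isnan(qc.clear_sky_index(5.0, 10.0, 1.0))

    def test_negative_swdr_nulled(self):
        assert np.isnan(qc.clear_sky_index(-5.0, 500.0, 1.0))

    def test_clear_generator_day_has_unit_midday_csi(self, default_config):
        spec = ef.ScenarioSpec(seed=0, n_years=1).zero_noise()
        rec = ef.generate_halfhourly(spec)
        d = qc._with_solar(rec[(rec.site_id == "CT")
                               & (rec.layer == "ecosystem")], 39.94)
        csi = qc.clear_sky_index(d["SWDR"], d["sw_pot"],
                                 default_config.transmissivity)
        mid = ef.tower_io.midday_mask(d["timestamp"], default_config)
        assert np.allclose(csi[mid.to_numpy()], 1.0, atol=1e-12)


class TestMiddayAlbedo:
    def _frame(self, swdr, swur, precip=0.0):
        ts = pd.date_range("2020-06-01 00:30", periods=48, freq="30min")
        return pd.DataFrame({
            "timestamp": ts, "site_id": "CT", "layer": "ecosystem",
            "SWDR": swdr, "SWUR": swur, "precip": precip})

    def test_constant_ratio_recovered(self, default_config):
        swdr = 800.0 * np.ones(48)
        out = qc.midday_albedo_daily(self._frame(swdr, 0.18 * swdr),
                                     default_config)
        assert out["albedo"].iloc[0] == pytest.approx(0.18)

    def test_rainy_day_yields_null(self, default_config):
        swdr = 800.0 * np.ones(48)
        out = qc.midday_albedo_daily(
            self._frame(swdr, 0.18 * swdr, precip=0.1), default_config)
        assert out.empty or np.isnan(out["albedo"].iloc[0])

    def test_ramp_gives_mean_of_window_ratios(self, default_config):
        # albedo ramps 0.17 -> 0.19 across the day; the daily value is the
        # arithmetic mean of the ratios inside the 7-half-hour window
        swdr = 800.0 * np.ones(48)
        alpha = np.linspace(0.17, 0.19, 48)
        frame = self._frame(swdr, alpha * swdr)
        out = qc.midday_albedo_daily(frame, default_config)
        mid = ef.tower_io.midday_mask(frame["timestamp"], default_config)
        assert mid.sum() == 7
        assert out["albedo"].iloc[0] == pytest.approx(alpha[mid].mean())


class TestCombineSoilHeatFlux:
    @pytest.mark.parametrize("go,gc,f,expected", [
        (50.0, 20.0, 0.2, 44.0),
        (50.0, 20.0, 0.0, 50.0),
        (50.0, 20.0, 1.0, 20.0),
    ])
    def test_weighted_mean(self, go, gc, f, expected):
        assert qc.combine_soil_heat_flux(go, gc, f) == pytest.approx(expected)

    def test_null_propagates(self):
        assert np.isnan(qc.combine_soil_heat_flux(50.0, np.nan, 0.2))

    def test_bad_fraction_errors(self):
        with pytest.raises(ValueError):
            qc.combine_soil_heat_flux(50.0, 20.0, 1.5)


class TestDayFlags:
    def _one_day(self, le=None, precip=0.0):
        spec = ef.ScenarioSpec(seed=0, n_years=1).zero_noise()
        rec = ef.generate_halfhourly(spec)
        d = rec[(rec.site_id == "CT") & (rec.layer == "ecosystem")]
        d = d[ef.tower_io.day_of(d["timestamp"])
              == pd.Timestamp("2022-06-15")].copy()
        if le is not None:
            d["LE"] = le
        d["precip"] = precip
        return d

    def test_clean_day_passes(self, default_config):
        out = qc.day_flags(self._one_day(), default_config)
        assert bool(out["passes_missingness"].iloc[0])

    def test_mostly_missing_night_fails(self, default_config):
        d = self._one_day()
        mid = d["timestamp"] - pd.Timedelta(minutes=15)
        hour = mid.dt.hour + mid.dt.minute / 60.0
        night = qc._with_solar(d, 39.94)["sw_pot"].to_numpy() == 0
        night_idx = d.index[night]
        kill = night_idx[: int(0.7 * len(night_idx)) + 1]
        d.loc[kill, "LE"] = np.nan
        out = qc.day_flags(d, default_config)
        assert out["night_missing_fraction"].iloc[0] > 0.66
        assert not bool(out["passes_missingness"].iloc[0])

    def test_rainy_day_fails(self, default_config):
        out = qc.day_flags(self._one_day(precip=0.2), default_config)
        assert bool(out["is_rainy"].iloc[0])
        assert not bool(out["passes_missingness"].iloc[0])

    def test_pass_count_matches_brute_force_recount(self, noisy_records,
                                                    default_config):
        sub = noisy_records[(noisy_records.site_id == "NT")
                            & (noisy_records.layer == "ecosystem")]
        sub = sub[sub["timestamp"] < "2021-12-01"]
        flags = qc.day_flags(sub, default_config)
        # independent recount straight from the half-hourly table
        d = qc._with_solar(sub, 39.94)
        d["miss"] = d[list(qc.DECOMPOSITION_VARS)].isna().any(axis=1)
        n_pass = 0
        for date, grp in d.groupby("date"):
            day = grp[grp.sw_pot > 0]["miss"]
            night = grp[grp.sw_pot == 0]["miss"]
            ok = (day.mean() <= 0.66 and night.mean() <= 0.66
                  and not (grp["precip"].fillna(0) > 0).any())
            n_pass += ok
        assert flags["passes_missingness"].sum() == n_pass

    def test_filter_is_monotone_in_gaps(self, default_config):
        """Adding gaps can never turn a failing day into a passing one."""
        d = self._one_day()
        base = qc.day_flags(d, default_config)
        rng = np.random.default_rng(0)
        worse = d.copy()
        kill = rng.random(len(worse)) < 0.5
        worse.loc[worse.index[kill], "LE"] = np.nan
        after = qc.day_flags(worse, default_config)
        assert int(after["passes_missingness"].iloc[0]) <= int(
            base["passes_missingness"].iloc[0])


class TestDeltaTsAgreement:
    @pytest.mark.parametrize("obs,cal,keep", [
        (0.5, 1.9, True),
        (0.5, -0.5, False),   # sign mismatch
        (0.5, 2.6, False),    # difference over threshold
        (-1.0, -0.5, True),
        (0.0, 1.0, True),     # exact zero agrees with either sign
        (np.nan, 1.0, False),
    ])
    def test_rule(self, obs, cal, keep):
        assert bool(qc.delta_ts_agreement(obs, cal, 2.0)) is keep

    def test_crafted_table_retains_enumerable_subset(self):
        obs = np.array([0.5, 0.5, 0.5, -1.0, 0.0, 1.0, -2.0, 3.0, 0.1, -0.1])
        cal = np.array([1.9, -0.5, 2.6, -0.5, 1.0, 3.1, -3.9, 1.2, 0.1, 0.1])
        keep = qc.delta_ts_agreement(obs, cal, 2.0)
        assert keep.tolist() == [True, False, False, True, True, False,
                                 True, True, True, False]


class TestEnergyBalanceClosure:
    def test_exact_construction(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(50, 200, 60)
        daily = pd.DataFrame({"Rn": x + 20, "G": 20.0,
                              "LE": 0.5 * 0.88 * x, "H": 0.5 * 0.88 * x})
        out = qc.energy_balance_closure(daily)
        assert out["slope"] == pytest.approx(0.88, abs=1e-12)
        assert out["ratio_of_sums"] == pytest.approx(0.88, abs=1e-12)

    def test_perfect_closure(self):
        x = np.linspace(50, 200, 40)
        daily = pd.DataFrame({"Rn": x, "G": 0.0, "LE": 0.6 * x, "H": 0.4 * x})
        assert qc.energy_balance_closure(daily)["slope"] == pytest.approx(1.0)

    def test_insufficient_days_errors(self):
        daily = pd.DataFrame({"Rn": np.ones(10), "G": 0.0,
                              "LE": np.ones(10), "H": np.zeros(10)})
        with pytest.raises(ValueError, match="30"):
            qc.energy_balance_closure(daily)

    def test_noisy_generator_closure_recovered(self, noisy_results):
        closure = noisy_results["closure"].set_index(["site_id", "layer"])
        for site in ef.tower_io.SITES:
            assert closure.loc[(site, "ecosystem"), "slope"] == pytest.approx(
                0.88, abs=0.02)
            assert closure.loc[(site, "understory"), "slope"] == pytest.approx(
                0.60, abs=0.02)
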