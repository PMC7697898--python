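import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from polarsa import synthetic_data as sd
from polarsa.datasets import default_profiles


def simple_scenario(n_days=30, seed=0, **over) -> sd.MetScenario:
    base = dict(
        n_days=n_days,
        seed=seed,
        wind_regimes=[sd.WindRegime(90.0, 30.0, 3.0)],
        temp_noise_sd=1.0,
    )
    base.update(over)
    return sd.MetScenario(**base)


class TestMeteorology:
    def test_degenerate_amplitudes_give_constant_temperature(self):
        scen = simple_scenario(
            temp_seasonal_amp=0.0, temp_diurnal_amp=0.0, temp_noise_sd=0.0,
            temp_mean_annual=9.5,
        )
        met = sd.generate_meteorology(scen)
        np.testing.assert_allclose(met["temp"], 9.5, atol=1e-12)

    def test_zero_spread_regime_pins_wind_direction(self):
        scen = simple_scenario(wind_regimes=[sd.WindRegime(135.0, 0.0, 2.0)])
        met = sd.generate_meteorology(scen)
        np.testing.assert_allclose(met["wd"], 135.0, atol=1e-12)

    def test_determinism_contract(self):
        a = sd.generate_meteorology(simple_scenario(seed=3))
        b = sd.generate_meteorology(simple_scenario(seed=3))
        c = sd.generate_meteorology(simple_scenario(seed=4))
        pd.testing.assert_frame_equal(a, b)
        assert not a["ws"].equals(c["ws"])

    def test_physical_ranges(self):
        met = sd.generate_meteorology(simple_scenario(n_days=60))
        assert (met["ws"] >= 0).all()
        assert ((met["wd"] >= 0) & (met["wd"] < 360)).all()
        assert ((met["rh"] >= 0) & (met["rh"] <= 100)).all()

    def test_calendar_starts_on_monday(self):
        met = sd.generate_meteorology(simple_scenario())
        assert met["timestamp"].iloc[0].dayofweek == 0

    def test_invalid_weights_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.generate_meteorology(
                simple_scenario(wind_regimes=[sd.WindRegime(10.0, 5.0, 2.0, weight=0.0)])
            )

    def test_uncovered_hours_rejected(self):
        scen = simple_scenario(
            wind_regimes=[sd.WindRegime(10.0, 5.0, 2.0, hour_window=(0, 11))]
        )
        with pytest.raises(sd.ConfigurationError, match="no active wind regime"):
            sd.generate_meteorology(scen)


class TestSourceContributions:
    def test_rwb_all_zero_when_unparameterized(self):
        met = sd.generate_meteorology(simple_scenario())
        arch = replace(sd.default_rwb(), base_level=0.0, temp_sensitivity=0.0)
        truth = sd.generate_source_contributions(met, [arch])
        np.testing.assert_allclose(truth.source("rwb", "pm10"), 0.0)

    def test_aeolian_zero_below_threshold_and_power_law_above(self):
        scen = simple_scenario(wind_regimes=[sd.WindRegime(90.0, 10.0, 4.0)])
        met = sd.generate_meteorology(scen)
        arch = sd.default_aeolian(base_level=2.0)
        truth = sd.generate_source_contributions(met, [arch])
        pm10 = truth.source("aeolian", "pm10").to_numpy()
        ws = met["ws"].to_numpy()
        below = ws < arch.ws_threshold
        assert below.any() and (~below).any()
        np.testing.assert_allclose(pm10[below], 0.0)
        expected = arch.base_level * (ws[~below] - arch.ws_threshold) ** arch.ws_exponent
        np.testing.assert_allclose(pm10[~below], expected, rtol=1e-12)

    def test_traffic_weekend_ratio_recovered_over_two_years(self):
        scen = simple_scenario(n_days=730)
        met = sd.generate_meteorology(scen)
        arch = sd.default_traffic()
        assert arch.weekend_factor == 0.6
        truth = sd.generate_source_contributions(met, [arch])
        pm10 = truth.source("traffic", "pm10")
        weekend = pd.DatetimeIndex(met["timestamp"]).dayofweek >= 5
        ratio = pm10[weekend].mean() / pm10[~weekend].mean()
        assert abs(ratio - 0.6) <= 0.02

    def test_industrial_confined_to_sector_and_activation(self):
        met = sd.generate_meteorology(simple_scenario(n_days=90))
        arch = sd.default_industrial(stack_sector=(60.0, 120.0))
        truth = sd.generate_source_contributions(met, [arch])
        pm10 = truth.source("industrial", "pm10").to_numpy()
        wd, ws = met["wd"].to_numpy(), met["ws"].to_numpy()
        on = (wd >= 60) & (wd <= 120) & (ws >= arch.ws_activation)
        assert (pm10[~on] == 0).all()
        assert (pm10[on] > 0).all()

    def test_rwb_insensitive_to_temperature_above_threshold(self):
        met = sd.generate_meteorology(
            simple_scenario(temp_mean_annual=25.0, temp_seasonal_amp=2.0,
                            temp_diurnal_amp=2.0, temp_noise_sd=0.0)
        )
        assert (met["temp"] > 15).all()
        truth = sd.generate_source_contributions(met, [sd.default_rwb()])
        pm10 = truth.source("rwb", "pm10")
        # only the (deterministic) diurnal/weekend/calm shape remains;
        # regressing on temperature must give no heating signal
        hour0 = pm10[pd.DatetimeIndex(met["timestamp"]).hour == 3]
        ws0 = met.loc[pd.DatetimeIndex(met["timestamp"]).hour == 3, "ws"]
        base = hour0 / (1 + sd.default_rwb().calm_amplification * np.exp(-ws0))
        assert base.round(9).nunique() <= 2  # weekday vs weekend level only

    def test_winter_pm25_monotone_in_rwb_sensitivity(self):
        scen = simple_scenario(n_days=365)
        met = sd.generate_meteorology(scen)
        winter = pd.DatetimeIndex(met["timestamp"]).month.isin([6, 7, 8])
        totals = []
        for sens in (1.0, 2.0, 4.0):
            truth = sd.generate_source_contributions(
                met, [sd.default_rwb(temp_sensitivity=sens)], seed=5
            )
            totals.append(truth.total("pm25")[np.asarray(winter)].sum())
        assert totals[0] <= totals[1] <= totals[2]

    def test_traffic_diurnal_peaks_inside_rush_windows(self):
        met = sd.generate_meteorology(simple_scenario(n_days=60))
        truth = sd.generate_source_contributions(met, [sd.default_traffic()])
        diurnal = truth.source("traffic", "pm10").groupby(
            pd.DatetimeIndex(met["timestamp"]).hour
        ).mean()
        top2 = set(diurnal.sort_values(ascending=False).index[:2])
        assert all(6 <= h <= 10 or 16 <= h <= 21 for h in top2)

    def test_duplicate_archetype_names_rejected(self):
        met = sd.generate_meteorology(simple_scenario(n_days=2))
        with pytest.raises(sd.ConfigurationError, match="unique"):
            sd.generate_source_contributions(met, [sd.default_rwb(), sd.default_rwb()])


class TestAssembleObservations:
    def test_zero_noise_conserves_mass_exactly(self):
        met = sd.generate_meteorology(simple_scenario(n_days=30))
        truth = sd.generate_source_contributions(
            met, [sd.default_traffic(), sd.default_rwb()]
        )
        table = sd.assemble_observations(met, truth, noise_cv=0.0)
        for pollutant in ("pm25", "pm10", "nox", "co"):
            np.testing.assert_allclose(
                table[pollutant], truth.total(pollutant), rtol=1e-12
            )

    def test_single_pure_fine_source_gives_pm25_equal_pm10(self):
        met = sd.generate_meteorology(simple_scenario(n_days=10))
        arch = replace(sd.default_rwb(), fine_coarse_ratio=1.0, fine_coarse_spread=0.0)
        truth = sd.generate_source_contributions(met, [arch])
        table = sd.assemble_observations(met, truth, noise_cv=0.0)
        np.testing.assert_allclose(table["pm25"], table["pm10"], rtol=1e-12)

    def test_noise_cv_recovered_at_large_n(self):
        met = sd.generate_meteorology(simple_scenario(n_days=420))
        truth = sd.generate_source_contributions(met, [sd.default_traffic()])
        table = sd.assemble_observations(met, truth, noise_cv=0.10, seed=11)
        rel = table["pm10"].to_numpy() / truth.total("pm10").to_numpy() - 1.0
        assert len(rel) >= 10_000
        assert abs(rel.std(ddof=1) - 0.10) <= 0.01
        assert abs(rel.mean()) <= 0.01

    def test_pm25_never_exceeds_pm10_and_clips_are_logged(self):
        met = sd.generate_meteorology(simple_scenario(n_days=60))
        arch = replace(sd.default_rwb(), fine_coarse_ratio=0.98, fine_coarse_spread=0.0)
        truth = sd.generate_source_contributions(met, [arch])
        table = sd.assemble_observations(met, truth, noise_cv=0.3, seed=2)
        assert (table["pm25"] <= table["pm10"]).all()
        assert table.attrs["pm25_clip_events"] > 0


class TestSpeciatedSampleGeneration:
    @pytest.fixture()
    def truth(self):
        met = sd.generate_meteorology(simple_scenario(n_days=70))
        return sd.generate_source_contributions(
            met, [sd.default_traffic(), sd.default_rwb()]
        )

    def test_weekly_schedule_counts(self, truth):
        schedule = sd.weekly_schedule(truth.data.index, n_weeks=8, days_per_week=5)
        assert len(schedule) == 8
        assert all(len(hours) == 120 for hours in schedule)
        samples, g_true = sd.generate_speciated_samples(
            truth, default_profiles(["traffic", "rwb"]), schedule, noise_cv=0.0
        )
        assert samples.X.shape == (8, 8)
        # each row averages exactly the 120 scheduled hourly truth values
        direct = truth.data[("rwb", "pm25")].loc[schedule[2]].mean()
        assert g_true.iloc[2]["rwb"] == pytest.approx(direct, rel=1e-12)

    def test_noise_free_single_source_unit_profile(self, truth):
        import polarsa.receptor_models as rm

        profiles = rm.ProfileMatrix(
            F=pd.DataFrame([[1.0, 0.0]], index=["rwb"], columns=["OC", "EC"])
        )
        schedule = sd.weekly_schedule(truth.data.index, n_weeks=4)
        samples, g_true = sd.generate_speciated_samples(
            truth, profiles, schedule, noise_cv=0.0
        )
        np.testing.assert_allclose(samples.X["OC"], g_true["rwb"], rtol=1e-12)
        np.testing.assert_allclose(samples.X["EC"], 0.0, atol=1e-12)

    def test_disjoint_tracers_round_trip_through_cmb(self, truth):
        import polarsa.receptor_models as rm

        profiles = rm.ProfileMatrix(
            F=pd.DataFrame(
                [[0.6, 0.0], [0.0, 0.5]], index=["traffic", "rwb"], columns=["A", "B"]
            )
        )
        schedule = sd.weekly_schedule(truth.data.index, n_weeks=6)
        samples, g_true = sd.generate_speciated_samples(
            truth, profiles, schedule, noise_cv=0.0
        )
        fit = rm.cmb_fit(samples, profiles)
        np.testing.assert_allclose(fit.G, g_true, rtol=1e-9)

    def test_empty_schedule_rejected(self, truth):
        with pytest.raises(sd.ConfigurationError, match="empty"):
            sd.generate_speciated_samples(
                truth, default_profiles(["rwb"]), [], noise_cv=0.0
            )
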