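"""Geolocator event detection: twilights, positions, flights, incubation, event tables."""

import numpy as np
import pandas as pd
import pytest

from marshwave import geolocator as geo
from marshwave import solar
from marshwave import synthetic as syn


def square_wave_light(days=5, rise_h=6, set_h=18, dt_min=10, level=64.0):
    t = np.arange(np.datetime64("2011-06-01T00:00:00", "s"),
                  np.datetime64("2011-06-01T00:00:00", "s") + np.timedelta64(days, "D"),
                  np.timedelta64(dt_min * 60, "s"))
    hour = (t - t.astype("datetime64[D]")).astype("timedelta64[s]").astype(float) / 3600.0
    light = np.where((hour >= rise_h) & (hour < set_h), level, 0.0)
    return pd.DataFrame({"timestamp": t, "light": light})


class TestTwilights:
    def test_square_wave_one_pair_per_day_at_expected_times(self):
        tw = geo.detect_twilights(square_wave_light(days=5), light_threshold=1.0)
        rises = tw[tw["kind"] == "rise"]["timestamp"]
        sets_ = tw[tw["kind"] == "set"]["timestamp"]
        assert len(rises) == 5 and len(sets_) == 5
        for r in rises:
            minutes = (np.datetime64(r, "s") - np.datetime64(r, "D")).astype(
                "timedelta64[s]").astype(float) / 60.0
            assert abs(minutes - 6 * 60) <= 10  # within one sampling interval
    def test_threshold_above_series_maximum_is_empty(self):
        with pytest.warns(UserWarning):
            tw = geo.detect_twilights(square_wave_light(), light_threshold=100.0)
        assert tw.empty

    def test_solar_track_crossings_match_closed_form_oracle(self):
        lat, lon = 39.27, -75.24
        script = syn.TrackScript("still", lat, lon, 94, 107, 127, 192, 216,
                                 incubation_bouts=(), flight_legs=(), seed=0)
        light, _c, _t = syn.gen_geolocator_track(script)
        sel = (light["timestamp"] >= np.datetime64("2011-05-15")) & (
            light["timestamp"] < np.datetime64("2011-05-25"))
        tw = geo.detect_twilights(light[sel].reset_index(drop=True))
        # effective zenith of the light template's threshold-1 crossing
        zen_eff = 90.0 - (-6.0 + 1.0 / 8.0)
        for _i, ev in tw.iterrows():
            doy = geo._doy(ev["timestamp"])
            errs = []
            # a sunset just past UTC midnight belongs to the previous solar day
            for d in (doy - 1, doy, doy + 1):
                r, s = solar.sunrise_sunset(lat, lon, 2011, d, zenith=zen_eff)
                oracle = r if ev["kind"] == "rise" else s
                if oracle is not None:
                    errs.append(abs((np.datetime64(ev["timestamp"], "s") - oracle).astype(
                        "timedelta64[s]").astype(float)))
            assert min(errs) <= 600  # one sampling interval


class TestOutlierFilter:
    def _events(self, minute_offsets, kind="rise", base="2011-05-01T09:30:00"):
        t0 = np.datetime64(base, "s")
        rows = [(t0 + np.timedelta64(i, "D") + np.timedelta64(int(off * 60), "s"), kind)
                for i, off in enumerate(minute_offsets)]
        df = pd.DataFrame(rows, columns=["timestamp", "kind"])
        df["edited"] = "kept"
        return df

    def test_constant_clock_times_nothing_removed(self):
        out = geo.filter_twilight_outliers(self._events([0] * 7))
        assert (out["edited"] == "kept").all()

    def test_single_displaced_event_removed(self):
        out = geo.filter_twilight_outliers(self._events([0, 0, 0, 60, 0, 0, 0]))
        assert list(out["edited"]) == ["kept"] * 3 + ["removed"] + ["kept"] * 3

    def test_gradual_seasonal_drift_survives(self):
        out = geo.filter_twilight_outliers(self._events([2 * i for i in range(20)]))
        assert (out["edited"] == "kept").all()

    def test_empty_input_passes_through(self):
        empty = pd.DataFrame(columns=["timestamp", "kind", "edited"])
        assert geo.filter_twilight_outliers(empty).empty


class TestThresholdPosition:
    def test_longitude_from_solar_noon(self):
        # Apr 15: equation of time is ~0 min
        rise = np.datetime64("2011-04-15T06:00:00")
        sset = np.datetime64("2011-04-15T18:00:00")
        p = geo.threshold_position(rise, sset)
        assert p.longitude == pytest.approx(0.0, abs=0.3)
        p75 = geo.threshold_position(rise + np.timedelta64(5, "h"), sset + np.timedelta64(5, "h"))
        assert p75.longitude == pytest.approx(-75.0, abs=0.3)

    def test_set_before_rise_raises(self):
        with pytest.raises(ValueError):
            geo.threshold_position(np.datetime64("2011-04-15T18:00:00"),
                                   np.datetime64("2011-04-15T06:00:00"))

    def test_round_trip_from_solar_oracle_sixty_days_from_equinox(self):
        lat, lon = 39.27, -75.24
        for doy in (139, 160, 325):  # mid-May, mid-June, late Nov
            r, s = solar.sunrise_sunset(lat, lon, 2011, doy, zenith=96.0)
            p = geo.threshold_position(r, s, zenith=96.0)
            assert p.longitude == pytest.approx(lon, abs=0.5)
            assert p.latitude == pytest.approx(lat, abs=2.0)

    def test_equinoctial_daylength_flags_latitude_undefined(self):
        rise = np.datetime64("2011-03-20T06:00:00")
        sset = np.datetime64("2011-03-20T18:01:00")
        p = geo.threshold_position(rise, sset)
        assert np.isnan(p.latitude) and np.isfinite(p.longitude)


class TestEquinoxMask:
    def test_mask_window_and_counts(self):
        days = pd.date_range("2011-01-01", "2011-12-31", freq="D")
        pos = pd.DataFrame({"timestamp": days.to_numpy(dtype="datetime64[s]"),
                            "longitude": -70.0, "latitude": 40.0})
        out = geo.mask_equinox(pos, half_window_days=40)
        # Mar 20 masked, Jun 21 untouched
        assert np.isnan(out.loc[out["timestamp"] == np.datetime64("2011-03-20T00:00:00", "s"),
                                "latitude"]).all()
        jun = out.loc[out["timestamp"] == np.datetime64("2011-06-21T00:00:00", "s")]
        assert jun["latitude"].iloc[0] == 40.0
        assert (out["longitude"] == -70.0).all()
        assert int(out["latitude"].isna().sum()) == 2 * (2 * 40 + 1)


class TestFlights:
    def _cond(self, wet):
        t = np.arange(np.datetime64("2011-07-01T00:00:00", "s"),
                      np.datetime64("2011-07-01T00:00:00", "s") + np.timedelta64(len(wet) * 600, "s"),
                      np.timedelta64(600, "s"))
        return pd.DataFrame({"timestamp": t, "wet": wet})

    def test_all_wet_is_empty(self):
        assert geo.classify_flights(self._cond(np.ones(500, dtype=int))).empty

    def test_single_96h_dry_run_duration(self):
        wet = np.ones(7 * 144, dtype=int)
        wet[144: 144 + 576] = 0  # 96 h at 10-min sampling
        fl = geo.classify_flights(self._cond(wet), min_dry_hours=20.0)
        assert len(fl) == 1
        assert fl["duration_hours"].iloc[0] == pytest.approx(96.0, abs=10 / 60)

    def test_runs_below_threshold_ignored(self):
        wet = np.ones(1000, dtype=int)
        wet[100:200] = 0  # ~16.7 h < 20 h
        assert geo.classify_flights(self._cond(wet), min_dry_hours=20.0).empty

    def test_idempotent_under_reapplication(self):
        rng = np.random.default_rng(0)
        wet = (rng.random(2000) < 0.8).astype(int)
        wet[300:500] = 0
        wet[1200:1420] = 0
        cond = self._cond(wet)
        fl1 = geo.classify_flights(cond, min_dry_hours=20.0)
        # rebuild a series that is dry exactly on the detected intervals
        wet2 = np.ones_like(wet)
        t = cond["timestamp"].to_numpy(dtype="datetime64[s]")
        for _i, row in fl1.iterrows():
            wet2[(t >= row["start"]) & (t < row["end"])] = 0
        fl2 = geo.classify_flights(self._cond(wet2), min_dry_hours=20.0)
        pd.testing.assert_frame_equal(fl1.reset_index(drop=True), fl2.reset_index(drop=True))


class TestIncubationAndEvents:
    def test_nest_initiation_recovered_from_scripted_shading(self, nj_track):
        light, _cond, truth = nj_track
        tw = geo.detect_twilights(light)
        bouts, nest = geo.detect_incubation(light, tw)
        assert nest == truth["nest_initiation"]
        assert len(bouts) > 20  # daily shading across the incubation period

    def test_event_table_matches_script(self, nj_track):
        light, cond, truth = nj_track
        ev = geo.analyze_track(light, cond, 39.2, -75.24, individual_id="nj_00")
        d = ev.to_dict()
        for key in ("spring_departure", "breeding_arrival", "nest_initiation",
                    "fall_departure", "winter_arrival"):
            assert d[key] is not None and abs(d[key] - truth[key]) <= 1

    def test_durations_are_exact_event_differences(self, nj_track):
        light, cond, _truth = nj_track
        ev = geo.analyze_track(light, cond, 39.2, -75.24)
        d = ev.to_dict()
        assert d["spring_migration_days"] == d["breeding_arrival"] - d["spring_departure"]
        assert d["nesting_period_days"] == d["fall_departure"] - d["nest_initiation"]
        assert d["wintering_days"] == d["spring_departure"] + 365 - d["winter_arrival"]

    def test_recovery_invariant_to_light_amplitude_scaling(self, nj_track):
        light, cond, _truth = nj_track
        scaled = light.copy()
        scaled["light"] = scaled["light"] * 10.0
        ev1 = geo.analyze_track(light, cond, 39.2, -75.24).to_dict()
        ev2 = geo.analyze_track(scaled, cond, 39.2, -75.24).to_dict()
        for key in ("spring_departure", "breeding_arrival", "nest_initiation",
                    "fall_departure", "winter_arrival"):
            assert ev1[key] == ev2[key]

    def test_missing_phases_leave_fields_undefined(self):
        empty_flights = pd.DataFrame(columns=["start", "end", "duration_hours"])
        pos = pd.DataFrame(columns=["timestamp", "longitude", "latitude"])
        ev = geo.build_event_table(empty_flights, pos, 39.2, -75.24)
        assert ev.spring_departure is None and ev.winter_arrival is None
        assert all(v is None for v in ev.durations().values())
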