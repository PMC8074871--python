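"""Daily feature engineering: arithmetic contracts and missingness semantics."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

import phenokit as pk
from phenokit.features import (
    MISSING_NO_DATA,
    MISSING_NOT_WORN,
    OK,
    accel_features,
    comm_features,
    heart_features,
    light_feature,
    power_feature,
    sleep_features,
    steps_features,
    taps_features,
    worn_overnight,
)
from phenokit.streams import load_app_mapping

from conftest import DAY0_MS, mk_day

DATE = dt.date(2020, 4, 1)
MIN = 60_000


# ---------------------------------------------------------------------------
# Accelerometer


def test_accel_constant_gravity_has_zero_std():
    day = mk_day("accel", t=np.arange(10) * 500, x=np.zeros(10), y=np.zeros(10),
                 z=np.full(10, 9.81))
    (std, s1), (ddt, s2) = accel_features(day)
    assert s1 == OK and std == 0.0
    assert s2 == OK and ddt == 0.0


def test_accel_ddt_is_magnitude_slope():
    # L goes 9.81 -> 10.81 over 0.5 s: |dL/dt| = 2.0 m/s^3
    day = mk_day("accel", t=np.array([0, 500]), x=np.zeros(2), y=np.zeros(2),
                 z=np.array([9.81, 10.81]))
    (_, _), (ddt, s) = accel_features(day)
    assert s == OK
    assert ddt == pytest.approx(2.0)


def test_accel_pairs_beyond_one_second_excluded():
    day = mk_day("accel", t=np.array([0, 500, 5000]), x=np.zeros(3), y=np.zeros(3),
                 z=np.array([9.81, 10.81, 50.0]))
    (_, _), (ddt, _) = accel_features(day)
    assert ddt == pytest.approx(2.0)  # the 4.5 s pair is ignored


def test_accel_single_record_is_missing():
    day = mk_day("accel", t=np.array([0]), x=[0.0], y=[0.0], z=[9.81])
    (v1, s1), (v2, s2) = accel_features(day)
    assert s1 == MISSING_NO_DATA and s2 == MISSING_NO_DATA
    assert accel_features(None)[0][1] == MISSING_NO_DATA


# ---------------------------------------------------------------------------
# Ambient light


def test_light_hourly_max_log1p():
    t = DAY0_MS + np.array([10 * MIN, 20 * MIN])  # same clock hour
    day = mk_day("ambient_light", t=t, lux=np.array([0.0, 99.0]))
    v, s = light_feature(day)
    assert s == OK
    assert v == pytest.approx(math.log(100.0), abs=1e-9)


def test_light_all_zero_lux_gives_zero():
    t = DAY0_MS + np.arange(4) * 3_600_000
    day = mk_day("ambient_light", t=t, lux=np.zeros(4))
    assert light_feature(day)[0] == 0.0


def test_light_daily_value_is_mean_of_hourly_maxima():
    t = DAY0_MS + np.array([0, 3_600_000])
    lux = np.array([math.e**2 - 1, math.e**4 - 1])  # h-maxima log1p 2 and 4
    day = mk_day("ambient_light", t=t, lux=lux)
    assert light_feature(day)[0] == pytest.approx(3.0)
    assert light_feature(None)[1] == MISSING_NO_DATA


# ---------------------------------------------------------------------------
# Power state


def test_screen_on_count_divided_by_24():
    ev = ["screen_on"] * 48
    day = mk_day("power_state", t=np.arange(48) * MIN, event=ev)
    assert power_feature(day) == (2.0, OK)


def test_power_empty_present_is_zero_not_missing():
    assert power_feature(mk_day("power_state")) == (0.0, OK)
    day = mk_day("power_state", t=np.array([0]), event=["screen_off"])
    assert power_feature(day) == (0.0, OK)
    assert power_feature(None)[1] == MISSING_NO_DATA


# ---------------------------------------------------------------------------
# Taps


@pytest.fixture(scope="module")
def mapping():
    return load_app_mapping()


def test_taps_unique_apps_and_class_counts(mapping):
    apps = ["sg.app.video"] * 10 + ["sg.app.chat", "sg.app.maps"]
    day = mk_day("taps_log", t=np.arange(12) * 1000, app_id=apps,
                 key_token=["none"] * 12)
    out = taps_features(day, mapping)
    assert out["n_unique_apps"] == (3.0, OK)
    assert out["n_taps_in_entertainment"] == (10.0, OK)
    assert out["n_taps_in_social_messenger"] == (1.0, OK)


def test_taps_delete_backspace_count(mapping):
    toks = ["backspace", "backspace", "delete", "alphabetic", "none"]
    day = mk_day("taps_log", t=np.arange(5) * 1000, app_id=["sg.app.chat"] * 5,
                 key_token=toks)
    assert taps_features(day, mapping)["n_delete_backspace"] == (3.0, OK)


def test_taps_absent_vs_empty(mapping):
    assert taps_features(None, mapping)["n_unique_apps"][1] == MISSING_NO_DATA
    assert taps_features(mk_day("taps_log"), mapping)["n_unique_apps"] == (0.0, OK)


# ---------------------------------------------------------------------------
# Communication


def _call_day(durations, directions=None):
    n = len(durations)
    directions = directions or ["incoming"] * n
    return mk_day("call_log", t=np.arange(n) * 1000, channel=["call"] * n,
                  direction=directions, counterparty=["h-x"] * n,
                  duration_s=np.array(durations, dtype=float))


def test_calls_longer_than_one_minute_strict():
    out = comm_features(_call_day([30.0, 61.0, 600.0]), None, None, None)
    assert out["n_calls_gt_1min"] == (2.0, OK)
    # 60 s exactly does not count
    out = comm_features(_call_day([60.0]), None, None, None)
    assert out["n_calls_gt_1min"] == (0.0, OK)


def test_messages_exchanged_across_channels():
    sms = mk_day("sms_log", t=np.arange(2) * 1000, channel=["sms"] * 2,
                 direction=["outgoing", "outgoing"], counterparty=["h-x"] * 2,
                 length_chars=np.array([10, 20]))
    app = mk_day("sociability_msg_log", t=np.arange(3) * 1000,
                 channel=["app_msg"] * 3, direction=["incoming"] * 3,
                 counterparty=["h-x"] * 3, length_chars=np.array([5, 5, 5]))
    out = comm_features(None, sms, None, app)
    assert out["n_msgs_exchanged"] == (5.0, OK)


def test_missed_calls_count_nowhere():
    day = _call_day([0.0, 120.0], ["missed", "incoming"])
    out = comm_features(day, None, None, None)
    assert out["n_incoming_calls"] == (1.0, OK)
    assert out["n_calls_gt_1min"] == (1.0, OK)


def test_all_comm_files_empty_but_present_give_zero_counts():
    out = comm_features(mk_day("call_log"), mk_day("sms_log"),
                        mk_day("sociability_call_log"), mk_day("sociability_msg_log"))
    assert all(v == (0.0, OK) for v in out.values())


def test_all_comm_files_absent_are_missing():
    out = comm_features(None, None, None, None)
    assert all(s == MISSING_NO_DATA for _, s in out.values())


# ---------------------------------------------------------------------------
# Steps / heart / worn / sleep


def test_steps_totals_and_walk_minutes():
    t = DAY0_MS + np.arange(4) * MIN
    day = mk_day("steps", t=t, n_steps=np.array([0, 5, 12, 30]),
                 interval_s=np.full(4, 60.0))
    assert steps_features(day, walk_threshold=10) == ((47.0, OK), (2.0, OK))
    assert steps_features(day, walk_threshold=1) == ((47.0, OK), (3.0, OK))


def test_steps_all_zero_and_not_worn():
    t = DAY0_MS + np.arange(3) * MIN
    day = mk_day("steps", t=t, n_steps=np.zeros(3, dtype=int),
                 interval_s=np.full(3, 60.0))
    assert steps_features(day) == ((0.0, OK), (0.0, OK))
    v, s = steps_features(None, day_worn=False)[0]
    assert s == MISSING_NOT_WORN
    assert steps_features(None, day_worn=True)[0] == (0.0, OK)


def test_heart_duration_weighted_mean_and_min():
    day = mk_day("heart", t=np.arange(3) * 300_000,
                 bpm=np.array([60.0, 55.0, 70.0]), interval_s=np.full(3, 300.0))
    (mean, s1), (mn, s2), cov = heart_features(day)
    assert mean == pytest.approx(61.6667, abs=1e-3)
    assert mn == 55.0
    assert cov == pytest.approx(15.0)
    assert heart_features(None)[0][1] == MISSING_NOT_WORN


def test_heart_single_sample():
    day = mk_day("heart", t=np.array([0]), bpm=np.array([72.0]),
                 interval_s=np.array([300.0]))
    (mean, _), (mn, _), _ = heart_features(day)
    assert mean == mn == 72.0


def _heart_cover(start_min, end_min, date=DATE, step=5):
    mins = np.arange(start_min, end_min, step)
    return mk_day("heart", date=date, t=DAY0_MS + mins * MIN,
                  bpm=np.full(mins.size, 60.0),
                  interval_s=np.full(mins.size, step * 60.0))


def test_worn_overnight_full_coverage_true():
    prev = _heart_cover(0, 1440, DATE - dt.timedelta(days=1))
    prev.records["t"] -= 86_400_000
    today = _heart_cover(0, 1440)
    assert worn_overnight(today, prev, DATE) is True


def test_worn_overnight_no_heart_false():
    assert worn_overnight(None, None, DATE) is False


def test_worn_overnight_boundary_allowance_inclusive():
    # coverage 00:00-08:00 today only: the 22:00-24:00 gap is exactly 120 min
    today = _heart_cover(0, 8 * 60)
    assert worn_overnight(today, None, DATE, allowance_min=120.0) is True
    assert worn_overnight(today, None, DATE, allowance_min=119.0) is False


def _sleep_day(episodes):
    """episodes: list of (start_min_rel_day0, bed_min, asleep_min)."""
    rows = {k: [] for k in ("t", "seg_end", "stage", "episode_id",
                            "episode_start", "episode_end", "is_main_sleep")}
    for i, (start, bed, asleep) in enumerate(episodes):
        s = DAY0_MS + start * MIN
        rows["t"] += [s, s + asleep * MIN]
        rows["seg_end"] += [s + asleep * MIN, s + bed * MIN]
        rows["stage"] += ["asleep", "wake"]
        rows["episode_id"] += [i, i]
        rows["episode_start"] += [s, s]
        rows["episode_end"] += [s + bed * MIN, s + bed * MIN]
        rows["is_main_sleep"] += [i == 0, i == 0]
    return mk_day("sleep", t=np.array(rows["t"]),
                  seg_end=np.array(rows["seg_end"]), stage=rows["stage"],
                  episode_id=np.array(rows["episode_id"]),
                  episode_start=np.array(rows["episode_start"]),
                  episode_end=np.array(rows["episode_end"]),
                  is_main_sleep=np.array(rows["is_main_sleep"]))


def test_sleep_single_episode_total_and_efficiency():
    day = _sleep_day([(-120, 480, 432)])
    (total, s1), (eff, s2) = sleep_features(day, worn=True)
    assert (total, eff) == (pytest.approx(7.2), pytest.approx(90.0))


def test_sleep_two_episode_weighted_efficiency():
    day = _sleep_day([(-300, 300, 270), (600, 100, 90)])
    (total, _), (eff, _) = sleep_features(day, worn=True)
    assert total == pytest.approx(6.0)
    assert eff == pytest.approx(90.0)


def test_sleep_absent_depends_on_worn_state():
    (v, s1), (_, s2) = sleep_features(None, worn=False)
    assert s1 == s2 == MISSING_NOT_WORN
    (total, s1), (_, s2) = sleep_features(None, worn=True)
    assert (total, s1) == (0.0, OK)
    assert s2 == MISSING_NO_DATA


def test_sleep_overlapping_episodes_rejected():
    day = _sleep_day([(0, 300, 270), (100, 300, 270)])
    with pytest.raises(ValueError, match="overlap"):
        sleep_features(day, worn=True)


# ---------------------------------------------------------------------------
# Daily table


def test_daily_table_shape_and_determinism(small_cohort, small_daily):
    n = len(small_cohort.participants) * small_cohort.config.n_days
    assert len(small_daily) == n
    again = pk.build_daily_table(small_cohort)
    pd.testing.assert_frame_equal(small_daily, again)


def test_nonwear_days_marked_not_worn(small_cohort, small_daily):
    """Every planted non-wear day carries missing_not_worn for the wearable
    features, never zeros."""
    missing = small_cohort.missing_days
    nonwear = missing[missing.stream == "heart"][["participant_id", "date"]]
    assert len(nonwear) > 0
    merged = small_daily.merge(nonwear, on=["participant_id", "date"])
    assert (merged["sleep_total_hrs__status"] == MISSING_NOT_WORN).all()
    assert (merged["hr_mean__status"] == MISSING_NOT_WORN).all()
    assert (merged["daily_n_steps__status"] == MISSING_NOT_WORN).all()


def test_absent_phone_stream_is_missing_not_zero(small_cohort, small_daily):
    missing = small_cohort.missing_days
    gps_absent = missing[missing.stream == "gps"][["participant_id", "date"]]
    if len(gps_absent):
        merged = small_daily.merge(gps_absent, on=["participant_id", "date"])
        assert (merged["hometime_min__status"] == MISSING_NO_DATA).all()
        assert merged["hometime_min"].isna().all()
    taps_absent = missing[missing.stream == "taps_log"][["participant_id", "date"]]
    if len(taps_absent):
        merged = small_daily.merge(taps_absent, on=["participant_id", "date"])
        assert (merged["n_unique_apps__status"] == MISSING_NO_DATA).all()


def test_daily_table_respects_range_invariants(small_daily):
    d = small_daily
    assert d["hometime_min"].dropna().between(0, 1440).all()
    assert d["time_away_from_home_min"].dropna().between(0, 1440).all()
    assert ((d["hometime_min"] + d["time_away_from_home_min"]).dropna() <= 1440).all()
    assert d["sleep_mean_efficiency"].dropna().between(0, 100).all()
    assert (d["radius_of_gyration_m"].dropna() >= 0).all()
    for c in ["n_incoming_calls", "n_msgs_exchanged", "daily_n_steps",
              "n_unique_apps", "n_taps_in_entertainment"]:
        assert (d[c].dropna() >= 0).all()


def test_daily_table_from_disk_matches_in_memory(tmp_path):
    cfg = pk.default_cohort_config(2, 8, seed=21, with_effect=False)
    cohort = pk.generate_cohort(cfg, seed=21, out_dir=tmp_path)
    mem = pk.build_daily_table(cohort)
    enrollment = pd.read_csv(tmp_path / "enrollment.csv")
    disk = pk.build_daily_table(tmp_path, enrollment=enrollment)
    pd.testing.assert_frame_equal(
        mem.reset_index(drop=True), disk.reset_index(drop=True))
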