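"""Synthetic cohort generator: determinism, planted truth, missingness."""

import datetime as dt
import hashlib
import math

import numpy as np
import pytest

import phenokit as pk
from phenokit.simulate import (
    CohortConfig,
    MissingnessConfig,
    ParticipantProfile,
    RegimeEffect,
    make_profiles,
    planted_truth,
    presence_truth,
)
from phenokit.streams import WEARABLE_STREAMS


def _dataset_hash(root):
    h = hashlib.sha256()
    for f in sorted(root.rglob("*.csv")):
        h.update(str(f.relative_to(root)).encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def test_same_seed_gives_byte_identical_dataset(tmp_path):
    cfg = pk.default_cohort_config(2, 6, seed=3)
    pk.generate_cohort(cfg, seed=3, out_dir=tmp_path / "a")
    pk.generate_cohort(cfg, seed=3, out_dir=tmp_path / "b")
    assert _dataset_hash(tmp_path / "a") == _dataset_hash(tmp_path / "b")


def test_different_seed_changes_dataset(tmp_path):
    cfg = pk.default_cohort_config(1, 4, seed=3)
    pk.generate_cohort(cfg, seed=3, out_dir=tmp_path / "a")
    pk.generate_cohort(cfg, seed=4, out_dir=tmp_path / "b")
    assert _dataset_hash(tmp_path / "a") != _dataset_hash(tmp_path / "b")


def test_full_nonwear_removes_all_wearable_records():
    prof = make_profiles(1, 0)[0]
    miss = MissingnessConfig(p_nonwear_day=1.0)
    data = pk.generate_participant(prof, 8, None, miss, seed=1)
    for streams in data.days.values():
        for s in WEARABLE_STREAMS:
            assert s not in streams


def test_steps_multiplier_zero_zeroes_post_days():
    prof = make_profiles(1, 0)[0]
    miss = MissingnessConfig(0.0, 0.0, (1, 2), 0.0, 0.0)
    effect = RegimeEffect(changepoint_day=3, multipliers={"steps": 0.0})
    data = pk.generate_participant(prof, 6, effect, miss, seed=2)
    dates = sorted(data.days)
    for i, date in enumerate(dates):
        total = data.days[date]["steps"].records["n_steps"].sum()
        if i >= 3:
            assert total == 0
        else:
            assert total > 0


def test_manifest_missing_days_match_disk(tmp_path):
    cfg = pk.default_cohort_config(2, 10, seed=9)
    cohort = pk.generate_cohort(cfg, seed=9, out_dir=tmp_path)
    on_disk = set()
    for f in tmp_path.rglob("*.csv"):
        if f.parent.parent.parent == tmp_path:
            on_disk.add((f.parent.parent.name, f.parent.name,
                         dt.date.fromisoformat(f.stem)))
    planted_absent = {(r.participant_id, r.stream, r.date)
                      for r in cohort.missing_days.itertuples()}
    # bookkeeping identity: absent on disk == planted missing list
    from phenokit.streams import ALL_STREAMS
    all_cells = {(pid, s, d) for pid in cohort.participants
                 for s in ALL_STREAMS for d in cohort.dates}
    assert all_cells - on_disk == planted_absent


def test_duplicate_participant_ids_rejected():
    profs = make_profiles(2, 0)
    profs[1].participant_id = profs[0].participant_id
    with pytest.raises(ValueError, match="duplicate"):
        CohortConfig(profiles=profs)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        MissingnessConfig(p_file_absent=1.5)
    with pytest.raises(ValueError):
        RegimeEffect(1, {"steps": -0.1})
    with pytest.raises(ValueError):
        ParticipantProfile("P0", efficiency_range=(90, 120))


# ---------------------------------------------------------------------------
# Planted truth


def test_truth_steps_ratio_equals_multiplier():
    prof = make_profiles(1, 0)[0]
    prof.steps_weekend_multiplier = 1.0  # flat week so the ratio is exact
    cfg = CohortConfig(profiles=[prof], n_days=90,
                       effect=RegimeEffect(45, {"steps": 0.6}))
    man = planted_truth(cfg)
    row = man[man.metric == "daily_n_steps"].iloc[0]
    assert row.post_expected / row.pre_expected == pytest.approx(0.6, rel=1e-12)
    assert row.direction == -1


def test_truth_no_effect_means_pre_equals_post():
    cfg = CohortConfig(profiles=make_profiles(2, 1), n_days=60, effect=None)
    man = planted_truth(cfg)
    closed = man.dropna(subset=["pre_expected"])
    # weekday mix differs between the two halves only for steps-family rows
    flat = closed[~closed.metric.isin(["daily_n_steps", "daily_n_mins_walk"])]
    assert np.allclose(flat.pre_expected, flat.post_expected)
    assert (man.direction[~man.metric.isin(
        ["daily_n_steps", "daily_n_mins_walk"])] == 0).all()


def test_truth_sleep_total_is_duration_times_efficiency():
    prof = make_profiles(1, 2)[0]
    cfg = CohortConfig(profiles=[prof], n_days=30, effect=None)
    man = planted_truth(cfg)
    row = man[man.metric == "sleep_total_hrs"].iloc[0]
    eff_mean = sum(prof.efficiency_range) / 2
    assert row.pre_expected == pytest.approx(
        prof.sleep_duration_mean_h * eff_mean / 100.0)


# ---------------------------------------------------------------------------
# Moment recovery and structure


RECOVERY_METRICS = ["daily_n_steps", "daily_n_mins_walk", "sleep_total_hrs",
                    "sleep_mean_efficiency", "hometime_min",
                    "time_away_from_home_min", "hr_mean", "n_incoming_calls",
                    "n_msgs_exchanged", "hourly_n_screen_on",
                    "n_taps_in_entertainment", "n_unique_apps"]


@pytest.mark.parametrize("metric", RECOVERY_METRICS)
def test_feature_mean_recovers_planted_truth(recovery_cohort, recovery_daily, metric):
    """Empirical daily mean over 150 generated days sits within 3 Monte-Carlo
    standard errors of the closed-form planted expectation."""
    man = recovery_cohort.manifest
    for pid in recovery_cohort.participants:
        v = recovery_daily[recovery_daily.participant_id == pid][metric].dropna()
        assert len(v) >= 100
        exp = man[(man.participant_id == pid) & (man.metric == metric)
                  ].pre_expected.iloc[0]
        se = v.std() / math.sqrt(len(v))
        assert abs(v.mean() - exp) <= 3 * se + 1e-9, (
            f"{pid} {metric}: emp={v.mean():.3f} exp={exp:.3f} se={se:.4f}")


def test_weekly_periodicity_in_steps():
    """With a weekend multiplier, the daily step series autocorrelates more
    strongly at lag 7 than at lag 5."""
    prof = make_profiles(1, 4)[0]
    prof.steps_weekend_multiplier = 1.5
    miss = MissingnessConfig(0, 0, (1, 2), 0, 0)
    data = pk.generate_participant(prof, 180, None, miss, seed=4)
    totals = np.array([data.days[d]["steps"].records["n_steps"].sum()
                       for d in sorted(data.days)], dtype=float)
    x = totals - totals.mean()

    def acf(lag):
        return float(np.dot(x[:-lag], x[lag:]) / np.dot(x, x))

    assert acf(7) > acf(5)


def test_worn_coupling_between_sleep_and_heart(small_cohort):
    """A sleep episode only ever appears on nights with heart-rate coverage;
    non-worn days have neither heart, steps, nor sleep."""
    for pdata in small_cohort.participants.values():
        for date, streams in pdata.days.items():
            has = {s: s in streams for s in WEARABLE_STREAMS}
            assert len(set(has.values())) == 1  # all or none
            if has["sleep"]:
                assert len(streams["heart"].records) > 0


def test_presence_truth_matches_config():
    cfg = pk.default_cohort_config(1, 5, seed=0)
    pt = presence_truth(cfg)
    mc = cfg.missingness
    phone = pt[pt.stream == "gps"].expected_presence.iloc[0]
    assert phone == pytest.approx(
        (1 - mc.p_phone_silent_day) * (1 - mc.p_file_absent))
    assert pt[pt.stream == "heart"].expected_presence.iloc[0] == pytest.approx(
        1 - mc.p_nonwear_day)
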