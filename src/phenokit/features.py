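"""Daily engineered behavioral features from raw stream-days.

Every feature is either a value or an explicit missing marker; the marker
distinguishes *missing_no_data* (the stream was not collected) from
*missing_not_worn* (the wearable was off).  An empty-but-present event file
is a real observation and yields 0 for count features — the completion
semantics that make "no calls today" different from "no call log today".

The wearable ambiguity ("did they not sleep, or not wear the device to
bed?") is resolved from heart-rate coverage: heart epochs are recorded
continually while the device is worn, so a night window missing more than an
allotted allowance of coverage is ruled not-worn and sleep features are
marked ``missing_not_worn`` rather than zero.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mobility as mob
from .streams import (
    APP_CLASSES,
    StreamDay,
    classify_app,
    load_app_mapping,
    read_stream_day,
    scan_dataset,
)

log = logging.getLogger(__name__)

OK = "ok"
MISSING_NO_DATA = "missing_no_data"
MISSING_NOT_WORN = "missing_not_worn"

DAY_MS = 86_400_000
MIN_MS = 60_000

#: canonical study feature names for reports (dotted raw-stream style)
DISPLAY_NAMES = {
    "accel_L_std": "accel_L_std",
    "accel_ddt_max": "accel_ddt_max",
    "ambient_hourly_max_log1p_lux": "ambientLight.hourly_max_log1p_lux",
    "n_incoming_calls": "callLog_Incoming Call",
    "hometime_min": "gps-mobility_Hometime / mins",
    "sig_locs_visited": "gps-mobility_SigLocsVisited",
    "hourly_n_screen_on": "powerState.hourly_n_screen_on",
    "n_unique_apps": "tapsLog.daily_n_unique_apps",
    "n_taps_in_entertainment": "tapsLog.daily_n_taps_in_entertainment",
    "daily_n_steps": "steps.daily_n_steps",
    "daily_n_mins_walk": "steps.daily_n_mins_walk",
    "hr_mean": "heart.daily_HR_mean",
    "hr_min": "heart.daily_HR_min",
    "sleep_total_hrs": "sleep_total_hrs",
    "sleep_mean_efficiency": "sleep_mean_efficiency",
}


@dataclass
class FeatureConfig:
    tz_offset_hours: float = 8.0
    walk_threshold: int = 10            # steps/min that count as walking
    night_window: tuple[float, float] = (22.0, 8.0)  # local clock hours
    allowance_min: float = 120.0        # tolerated HR-coverage gap at night
    day_worn_min: float = 60.0          # HR minutes that count a day as worn
    screen_on_denominator_h: float = 24.0
    home_radius_m: float = 200.0
    gap_max_min: float = 30.0
    eps_m: float = 100.0
    min_dwell_min: float = 30.0
    rog_mode: str = "max"
    app_mapping: dict[str, str] | None = None

    def mapping(self) -> dict[str, str]:
        if self.app_mapping is None:
            self.app_mapping = load_app_mapping()
        return self.app_mapping


Value = tuple[float, str]  # (value, status); value is NaN unless status == OK


def _missing(status: str) -> Value:
    return (math.nan, status)


# ---------------------------------------------------------------------------
# Per-stream operations


def accel_features(day: StreamDay | None) -> tuple[Value, Value]:
    """(accel_L_std, accel_ddt_max): SD of the acceleration-vector length and
    the maximum absolute time derivative of that length over consecutive
    samples no more than 1 s apart."""
    if day is None:
        return _missing(MISSING_NO_DATA), _missing(MISSING_NO_DATA)
    r = day.records
    if len(r) < 2:
        return _missing(MISSING_NO_DATA), _missing(MISSING_NO_DATA)
    L = np.sqrt(r["x"].to_numpy() ** 2 + r["y"].to_numpy() ** 2 + r["z"].to_numpy() ** 2)
    l_std = (float(np.std(L, ddof=1)), OK)
    dt_s = np.diff(r["t"].to_numpy()) / 1000.0
    ok = (dt_s > 0) & (dt_s <= 1.0)
    if not ok.any():
        return l_std, _missing(MISSING_NO_DATA)
    ddt = np.abs(np.diff(L))[ok] / dt_s[ok]
    return l_std, (float(ddt.max()), OK)


def light_feature(day: StreamDay | None, tz_offset_hours: float = 8.0) -> Value:
    """Daily mean over clock hours (with data) of the hourly max of log(1+lux)."""
    if day is None or not len(day.records):
        return _missing(MISSING_NO_DATA)
    r = day.records
    hour = (((r["t"].to_numpy() + int(tz_offset_hours * 3_600_000)) % DAY_MS)
            // 3_600_000).astype(np.int64)
    loglux = np.log1p(r["lux"].to_numpy())
    hmax = np.full(24, -np.inf)
    np.maximum.at(hmax, hour, loglux)
    return (float(hmax[np.isfinite(hmax)].mean()), OK)


def power_feature(day: StreamDay | None, denominator_h: float = 24.0) -> Value:
    """Mean screen-on events per hour (total count / 24 by default)."""
    if day is None:
        return _missing(MISSING_NO_DATA)
    n_on = (int((day.records["event"].to_numpy() == "screen_on").sum())
            if len(day.records) else 0)
    return (n_on / denominator_h, OK)


def taps_features(day: StreamDay | None, mapping: dict[str, str]) -> dict[str, Value]:
    """Unique apps tapped, per-class tap counts, and delete+backspace count."""
    keys = ["n_unique_apps", *(f"n_taps_in_{c}" for c in APP_CLASSES), "n_delete_backspace"]
    if day is None:
        return {k: _missing(MISSING_NO_DATA) for k in keys}
    r = day.records
    out = {k: (0.0, OK) for k in keys}
    if not len(r):
        return out
    apps = r["app_id"].to_numpy()
    uniq, counts = np.unique(apps, return_counts=True)
    out["n_unique_apps"] = (float(uniq.size), OK)
    per_class = dict.fromkeys(APP_CLASSES, 0.0)
    for app, cnt in zip(uniq, counts):
        per_class[classify_app(app, mapping)] += float(cnt)
    for c in APP_CLASSES:
        out[f"n_taps_in_{c}"] = (per_class[c], OK)
    tok = r["key_token"].to_numpy()
    out["n_delete_backspace"] = (float(((tok == "delete") | (tok == "backspace")).sum()), OK)
    return out


def comm_features(
    call_log: StreamDay | None,
    sms_log: StreamDay | None,
    soc_call_log: StreamDay | None,
    soc_msg_log: StreamDay | None,
) -> dict[str, Value]:
    """Sociability counts across phone and messaging-app channels.

    Calls longer than one minute use a strict ``duration_s > 60`` rule; missed
    calls never count as incoming."""

    def _count(day, pred) -> float | None:
        if day is None:
            return None
        if not len(day.records):
            return 0.0
        return float(pred(day.records).sum())

    inc = _count(call_log, lambda r: r["direction"].to_numpy() == "incoming")
    outg = _count(call_log, lambda r: r["direction"].to_numpy() == "outgoing")
    msgs = [_count(d, lambda r: np.isin(r["direction"].to_numpy(),
                                        ("incoming", "outgoing")))
            for d in (sms_log, soc_msg_log)]
    long_calls = [_count(d, lambda r: (r["duration_s"].to_numpy() > 60)
                         & (r["direction"].to_numpy() != "missed"))
                  for d in (call_log, soc_call_log)]

    def _sum(parts) -> Value:
        vals = [p for p in parts if p is not None]
        if not vals:
            return _missing(MISSING_NO_DATA)
        return (float(sum(vals)), OK)

    return {
        "n_incoming_calls": _sum([inc]),
        "n_outgoing_calls": _sum([outg]),
        "n_msgs_exchanged": _sum(msgs),
        "n_calls_gt_1min": _sum(long_calls),
    }


def steps_features(
    day: StreamDay | None, walk_threshold: int = 10, day_worn: bool = True
) -> tuple[Value, Value]:
    """(daily_n_steps, daily_n_mins_walk) from minute-resolution step epochs."""
    if day is None or not len(day.records):
        if not day_worn:
            return _missing(MISSING_NOT_WORN), _missing(MISSING_NOT_WORN)
        return (0.0, OK), (0.0, OK)
    r = day.records
    # resample to minute resolution before thresholding
    minute = r["t"].to_numpy() // MIN_MS
    uniq, inv = np.unique(minute, return_inverse=True)
    per_min = np.zeros(uniq.size)
    np.add.at(per_min, inv, r["n_steps"].to_numpy())
    return (
        (float(per_min.sum()), OK),
        (float((per_min >= walk_threshold).sum()), OK),
    )


def heart_features(day: StreamDay | None) -> tuple[Value, Value, float]:
    """(hr_mean, hr_min, coverage_min): duration-weighted mean bpm, plain
    minimum, and minutes of the day covered by heart epochs."""
    if day is None or not len(day.records):
        return _missing(MISSING_NOT_WORN), _missing(MISSING_NOT_WORN), 0.0
    r = day.records
    w = r["interval_s"].to_numpy()
    bpm = r["bpm"].to_numpy()
    mean = float(np.average(bpm, weights=w))
    return (mean, OK), (float(bpm.min()), OK), float(w.sum() / 60.0)


def _hr_window_coverage_min(
    heart_days: list[StreamDay | None], win_start_ms: float, win_end_ms: float
) -> float:
    cov = 0.0
    for day in heart_days:
        if day is None or not len(day.records):
            continue
        t0 = day.records["t"].to_numpy(dtype=np.float64)
        t1 = t0 + day.records["interval_s"].to_numpy() * 1000.0
        lo = np.maximum(t0, win_start_ms)
        hi = np.minimum(t1, win_end_ms)
        cov += float(np.clip(hi - lo, 0, None).sum()) / MIN_MS
    return cov


def worn_overnight(
    heart_today: StreamDay | None,
    heart_prev: StreamDay | None,
    date: dt.date,
    tz_offset_hours: float = 8.0,
    night_window: tuple[float, float] = (22.0, 8.0),
    allowance_min: float = 120.0,
) -> bool:
    """True iff nocturnal heart-rate coverage gaps stay within the allowance.

    The night window runs from ``night_window[0]`` on the previous evening to
    ``night_window[1]`` on the morning of ``date`` (local clock); the boundary
    is inclusive: a gap exactly equal to the allowance still counts as worn.
    """
    day0 = (dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc).timestamp()
            * 1000 - tz_offset_hours * 3_600_000)
    start = day0 - DAY_MS + night_window[0] * 3_600_000
    end = day0 + night_window[1] * 3_600_000
    total_min = (end - start) / MIN_MS
    cov = _hr_window_coverage_min([heart_prev, heart_today], start, end)
    return (total_min - cov) <= allowance_min


def sleep_features(sleep: StreamDay | None, worn: bool) -> tuple[Value, Value]:
    """(sleep_total_hrs, sleep_mean_efficiency) over episodes ending this day.

    Episodes are filed under their wake date.  With no episodes the wearable
    worn-state decides: not worn => both missing_not_worn (a sleepless night
    cannot be distinguished from an unworn device); worn => genuinely no
    sleep, total 0 h and efficiency undefined."""
    has_records = sleep is not None and len(sleep.records)
    if not has_records:
        if not worn:
            return _missing(MISSING_NOT_WORN), _missing(MISSING_NOT_WORN)
        return (0.0, OK), _missing(MISSING_NO_DATA)
    r = sleep.records
    seg_min = (r["seg_end"].to_numpy() - r["t"].to_numpy()) / MIN_MS
    if (seg_min < 0).any():
        raise ValueError("sleep segment with negative duration")
    total_asleep_min = float(seg_min[(r["stage"].to_numpy() != "wake")].sum())
    ep_ids, first = np.unique(r["episode_id"].to_numpy(), return_index=True)
    starts = r["episode_start"].to_numpy()[first]
    ends = r["episode_end"].to_numpy()[first]
    order = np.argsort(starts)
    if np.any(starts[order][1:] < ends[order][:-1]):
        raise ValueError("overlapping sleep episodes")
    bed_min_total = float((ends - starts).sum() / MIN_MS)
    if bed_min_total <= 0:
        raise ValueError("sleep episode with nonpositive duration")
    # time-in-bed weighting makes the mean efficiency total-asleep over total-bed
    return (
        (total_asleep_min / 60.0, OK),
        (100.0 * total_asleep_min / bed_min_total, OK),
    )


# ---------------------------------------------------------------------------
# Daily table


def _split(v: Value) -> tuple[float, str]:
    return v


def compute_daily_features(
    get,  # callable (date, stream) -> StreamDay | None
    participant_id: str,
    dates: list[dt.date],
    clusters,
    home,
    cfg: FeatureConfig,
) -> list[dict]:
    mapping = cfg.mapping()
    rows = []
    for i, date in enumerate(dates):
        row: dict = {"participant_id": participant_id, "date": date}

        def put(name: str, v: Value):
            row[name] = v[0]
            row[name + "__status"] = v[1]

        l_std, ddt = accel_features(get(date, "accel"))
        put("accel_L_std", l_std)
        put("accel_ddt_max", ddt)
        put("ambient_hourly_max_log1p_lux",
            light_feature(get(date, "ambient_light"), cfg.tz_offset_hours))
        put("hourly_n_screen_on",
            power_feature(get(date, "power_state"), cfg.screen_on_denominator_h))
        for k, v in taps_features(get(date, "taps_log"), mapping).items():
            put(k, v)
        for k, v in comm_features(
            get(date, "call_log"), get(date, "sms_log"),
            get(date, "sociability_call_log"), get(date, "sociability_msg_log"),
        ).items():
            put(k, v)

        if home is not None:
            mobday = mob.daily_mobility(
                get(date, "gps"), home, clusters,
                home_radius_m=cfg.home_radius_m, gap_max_min=cfg.gap_max_min,
                eps_m=cfg.eps_m, rog_mode=cfg.rog_mode,
            )
        else:
            mobday = {k: math.nan for k in (
                "hometime_min", "time_away_from_home_min",
                "sig_locs_visited", "radius_of_gyration_m")}
        for k, v in mobday.items():
            put(k, (v, OK) if not math.isnan(v) else _missing(MISSING_NO_DATA))

        heart_today = get(date, "heart")
        heart_prev = get(date - dt.timedelta(days=1), "heart") if i > 0 else None
        hr_mean, hr_min, coverage = heart_features(heart_today)
        put("hr_mean", hr_mean)
        put("hr_min", hr_min)
        row["hr_coverage_min"] = coverage
        day_worn = coverage >= cfg.day_worn_min

        steps_v, walk_v = steps_features(
            get(date, "steps"), cfg.walk_threshold, day_worn=day_worn)
        put("daily_n_steps", steps_v)
        put("daily_n_mins_walk", walk_v)

        worn = worn_overnight(
            heart_today, heart_prev, date, cfg.tz_offset_hours,
            cfg.night_window, cfg.allowance_min,
        )
        row["worn_overnight"] = worn
        total_v, eff_v = sleep_features(get(date, "sleep"), worn)
        put("sleep_total_hrs", total_v)
        put("sleep_mean_efficiency", eff_v)
        rows.append(row)
    return rows


def build_daily_table(source, cfg: FeatureConfig | None = None,
                      enrollment: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per participant x enrolled date with every engineered feature.

    ``source`` is either a generated in-memory cohort or a dataset root
    directory in the package layout.  Deterministic given inputs and config.
    """
    cfg = cfg or FeatureConfig()
    from .simulate import Cohort  # local import to avoid cycle

    if isinstance(source, Cohort):
        participants = {
            pid: (pdata.get, sorted(pdata.days.keys()))
            for pid, pdata in source.participants.items()
        }
        dates_all = source.dates
        per_dates = {pid: dates_all for pid in participants}
    else:
        loaded = load_dataset(source)
        participants = {}
        per_dates = {}
        for pid, daymap in loaded.items():
            participants[pid] = (
                lambda date, stream, _m=daymap: _m.get(date, {}).get(stream),
                sorted(daymap.keys()),
            )
            per_dates[pid] = _enrolled_dates(pid, daymap, enrollment)

    all_rows = []
    for pid in sorted(participants):
        get, _ = participants[pid]
        dates = per_dates[pid]
        gps_days = [d for d in (get(x, "gps") for x in dates) if d is not None]
        clusters = mob.cluster_significant_locations(
            gps_days, eps_m=cfg.eps_m, min_dwell_min=cfg.min_dwell_min,
            gap_cap_min=cfg.gap_max_min, tz_offset_hours=cfg.tz_offset_hours,
        )
        home = mob.infer_home(clusters) if clusters else None
        all_rows.extend(
            compute_daily_features(get, pid, dates, clusters, home, cfg))
    return pd.DataFrame(all_rows)


def _enrolled_dates(pid, daymap, enrollment) -> list[dt.date]:
    if enrollment is not None:
        row = enrollment[enrollment["participant_id"] == pid]
        if len(row):
            start = dt.date.fromisoformat(str(row["start_date"].iloc[0]))
            end = dt.date.fromisoformat(str(row["end_date"].iloc[0]))
            return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    if not daymap:
        return []
    start, end = min(daymap), max(daymap)
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


def load_dataset(root) -> dict[str, dict[dt.date, dict[str, StreamDay]]]:
    """Read every stream-day CSV under ``root``; unknown stream directories are
    ignored with a warning, and parse rejections are logged per file."""
    out: dict[str, dict[dt.date, dict[str, StreamDay]]] = {}
    for pid, stream, date, path in scan_dataset(root):
        day = read_stream_day(path, stream, pid, date)
        if day.n_rejected:
            log.warning("%s: parsed %d records, rejected %d",
                        path, day.n_records, day.n_rejected)
        else:
            log.info("%s: parsed %d records", path, day.n_records)
        out.setdefault(pid, {}).setdefault(date, {})[stream] = day
    return out
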