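"""Seeded synthetic smartphone + wearable sensor cohorts with planted truth.

The generator emulates the statistical structure the downstream pipeline
assumes: diurnal and weekly behavioral periodicity, an instantaneous
level-shift regime change (a lockdown analogue), per-stream missingness
including wearable non-wear, and empty-but-present daily files for event
streams.  Every planted quantity with a closed form is recorded in a truth
manifest so recovery tests need no reference dataset.

Distributions are deliberately standard and fully declared: Poisson event
counts, lognormal daily totals, Gaussian clock times, Beta-scaled sleep
efficiency.  Within-day structure: a nightly sleep episode with staged
segments filed under its wake date, heart-rate epochs present exactly while
the device is worn, steps emitted in minute bouts, GPS samples on a 10-minute
grid at the currently occupied place, and event streams at Poisson times.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .streams import (
    ALL_STREAMS,
    PHONE_STREAMS,
    WEARABLE_STREAMS,
    StreamDay,
    empty_records,
    hash_counterparty,
    load_app_mapping,
    obfuscate_gps,
    sample_displacement,
    write_stream_day,
)

DAY_MS = 86_400_000
MIN_MS = 60_000
DEG_PER_M_LAT = 1.0 / 111_194.9  # R * pi/180 meters per degree


# ---------------------------------------------------------------------------
# Configuration types


@dataclass
class Place:
    """A regularly visited out-of-home location with a fixed daily time slot."""

    lat: float
    lon: float
    p_visit: float
    start_min: int  # local minute of day the visit starts (10-min grid)
    dur_min: int    # visit duration in minutes (10-min grid)


@dataclass
class ParticipantProfile:
    participant_id: str
    home: tuple[float, float] = (1.32, 103.82)
    places: list[Place] = field(default_factory=list)
    sleep_onset_mean_min: float = 23 * 60.0  # local clock minutes
    sleep_onset_sd_min: float = 40.0
    sleep_duration_mean_h: float = 7.5
    sleep_duration_sd_h: float = 0.8
    efficiency_range: tuple[float, float] = (88.0, 96.0)
    hr_baseline: float = 72.0
    hr_circadian_amp: float = 8.0
    steps_daily_median: float = 6000.0  # lognormal median of the daily total
    steps_sigma: float = 0.35           # lognormal shape (sd of log)
    steps_weekend_multiplier: float = 1.2
    comm_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMM_RATES))
    taps_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAPS_RATES))
    screen_on_hourly_profile: tuple[float, ...] = None  # 24 nonnegative rates
    light_day_lux: float = 400.0
    light_night_lux: float = 4.0
    light_sigma: float = 0.6
    accel_day_sd: float = 0.45
    accel_night_sd: float = 0.08

    def __post_init__(self) -> None:
        if self.screen_on_hourly_profile is None:
            self.screen_on_hourly_profile = DEFAULT_SCREEN_PROFILE
        for p in self.places:
            if not 0.0 <= p.p_visit <= 1.0:
                raise ValueError("place visit probability outside [0, 1]")
        lo, hi = self.efficiency_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValueError("efficiency_range must lie within [0, 100]")
        if any(r < 0 for r in self.comm_rates.values()):
            raise ValueError("negative communication rate")
        if any(r < 0 for r in self.taps_rates.values()):
            raise ValueError("negative taps rate")


DEFAULT_COMM_RATES = {
    "call_in": 1.2,
    "call_out": 1.5,
    "call_missed": 0.3,
    "sms_in": 3.0,
    "sms_out": 3.0,
    "app_call_in": 0.8,
    "app_call_out": 0.8,
    "app_msg_in": 12.0,
    "app_msg_out": 12.0,
}

DEFAULT_TAPS_RATES = {
    "social_messenger": 120.0,
    "social_media": 60.0,
    "entertainment": 90.0,
    "map_navigation": 8.0,
    "utility_tools": 40.0,
    "games": 30.0,
    "android_systems": 15.0,
}

DEFAULT_SCREEN_PROFILE = (
    0.3, 0.2, 0.1, 0.1, 0.1, 0.3,  # 00-05
    1.0, 3.0, 5.0, 6.0, 7.0, 8.0,  # 06-11
    8.0, 7.0, 7.0, 7.0, 7.0, 8.0,  # 12-17
    9.0, 10.0, 10.0, 9.0, 6.0, 3.0,  # 18-23
)

# key-token mixture for taps (navigation taps dominate)
KEY_TOKEN_P = {
    "none": 0.70,
    "alphabetic": 0.20,
    "numeric": 0.02,
    "punctuation": 0.03,
    "backspace": 0.025,
    "delete": 0.005,
    "enter": 0.02,
}


@dataclass
class RegimeEffect:
    """Instantaneous level shift applied from ``changepoint_day`` onward.

    ``multipliers`` maps feature families to ratios; families the generator
    understands: steps, away_prob, incoming_calls, screen_on, unique_apps,
    taps_entertainment, lux_day, accel_std, sleep_efficiency, hr.
    """

    changepoint_day: int
    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.multipliers.values()):
            raise ValueError("regime multipliers must be >= 0")


#: directions of the lockdown analogue, mirroring the observed study effects
DEFAULT_REGIME_MULTIPLIERS = {
    "steps": 0.6,
    "away_prob": 0.5,
    "incoming_calls": 0.5,
    "screen_on": 0.75,
    "unique_apps": 0.7,
    "taps_entertainment": 1.3,
    "lux_day": 0.7,
    "accel_std": 0.7,
    "sleep_efficiency": 0.985,
}


@dataclass
class MissingnessConfig:
    p_phone_silent_day: float = 0.02
    p_nonwear_day: float = 0.10
    nonwear_block_hours: tuple[float, float] = (1.0, 3.0)
    p_daytime_nonwear_block: float = 0.25
    p_file_absent: float = 0.03

    def __post_init__(self) -> None:
        for p in (self.p_phone_silent_day, self.p_nonwear_day,
                  self.p_daytime_nonwear_block, self.p_file_absent):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must lie in [0, 1]")
        lo, hi = self.nonwear_block_hours
        if not (0 <= lo <= hi <= 9):
            raise ValueError("nonwear block must fit inside the daytime window")


@dataclass
class CohortConfig:
    profiles: list[ParticipantProfile]
    n_days: int = 90
    start_date: dt.date = dt.date(2020, 2, 22)
    effect: RegimeEffect | None = None
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    tz_offset_hours: float = 8.0  # study timezone (Singapore)
    salt: str = "phenokit-study-salt"

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant ids")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def event_date(self) -> dt.date | None:
        if self.effect is None:
            return None
        return self.start_date + dt.timedelta(days=self.effect.changepoint_day)


# ---------------------------------------------------------------------------
# Profiles and default cohort


def make_profiles(n: int, seed: int) -> list[ParticipantProfile]:
    """Draw a population of participant profiles (the cohort's between-person
    heterogeneity); deterministic in the seed."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        home = (float(rng.uniform(1.26, 1.42)), float(rng.uniform(103.70, 103.95)))
        n_places = int(rng.integers(2, 4))
        places = []
        for j in range(n_places):
            ang = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(800, 4000)  # meters from home
            places.append(
                Place(
                    lat=home[0] + dist * math.sin(ang) * DEG_PER_M_LAT,
                    lon=home[1] + dist * math.cos(ang) * DEG_PER_M_LAT / math.cos(math.radians(home[0])),
                    p_visit=float(rng.uniform(0.3, 0.8)),
                    start_min=600 + 210 * j,
                    dur_min=int(rng.choice([90, 120, 150])),
                )
            )
        rate_scale = float(np.exp(rng.normal(0, 0.25)))
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i:03d}",
                home=home,
                places=places,
                sleep_onset_mean_min=float(rng.normal(23 * 60, 30)),
                sleep_duration_mean_h=float(rng.normal(7.5, 0.5)),
                efficiency_range=(float(rng.uniform(86, 90)), float(rng.uniform(93, 97))),
                hr_baseline=float(rng.normal(72, 5)),
                hr_circadian_amp=float(rng.uniform(6, 10)),
                steps_daily_median=float(rng.lognormal(math.log(6000), 0.3)),
                steps_weekend_multiplier=float(rng.uniform(1.0, 1.4)),
                comm_rates={k: v * rate_scale for k, v in DEFAULT_COMM_RATES.items()},
                taps_rates={k: v * rate_scale for k, v in DEFAULT_TAPS_RATES.items()},
                light_day_lux=float(rng.lognormal(math.log(400), 0.3)),
            )
        )
    return profiles


def default_cohort_config(
    n_participants: int = 22,
    n_days: int = 90,
    seed: int = 0,
    with_effect: bool = True,
    changepoint_day: int = 45,
    multipliers: dict[str, float] | None = None,
) -> CohortConfig:
    """The study conditions: 22 participants x 90 days with the lockdown
    analogue level shift at day 45 (the pre/post comparison design)."""
    effect = None
    if with_effect:
        effect = RegimeEffect(
            changepoint_day=changepoint_day,
            multipliers=dict(DEFAULT_REGIME_MULTIPLIERS if multipliers is None else multipliers),
        )
    return CohortConfig(
        profiles=make_profiles(n_participants, seed),
        n_days=n_days,
        effect=effect,
    )


# ---------------------------------------------------------------------------
# Cohort containers


@dataclass
class ParticipantData:
    profile: ParticipantProfile
    displacement: tuple[float, float]
    days: dict[dt.date, dict[str, StreamDay]]  # only files that are present

    def get(self, date: dt.date, stream: str) -> StreamDay | None:
        return self.days.get(date, {}).get(stream)


@dataclass
class Cohort:
    config: CohortConfig
    seed: int
    participants: dict[str, ParticipantData]
    manifest: pd.DataFrame       # planted per-feature expectations
    presence: pd.DataFrame       # participant_id, date, stream, file_present
    missing_days: pd.DataFrame   # planted absent stream-days

    @property
    def dates(self) -> list[dt.date]:
        c = self.config
        return [c.start_date + dt.timedelta(days=d) for d in range(c.n_days)]


# ---------------------------------------------------------------------------
# Per-participant generation


def _app_pools() -> dict[str, list[str]]:
    pools: dict[str, list[str]] = {}
    for app, cls in load_app_mapping().items():
        pools.setdefault(cls, []).append(app)
    for cls in pools:
        pools[cls].sort()
    return pools


_APP_POOLS = _app_pools()


def _mk_day(pid, stream, date, data: dict) -> StreamDay:
    t = np.asarray(data["t"])
    cols = {k: np.asarray(v) for k, v in data.items()}
    if t.size and np.any(np.diff(t) < 0):
        order = np.argsort(t, kind="stable")
        cols = {k: v[order] for k, v in cols.items()}
    return StreamDay(pid, stream, date, pd.DataFrame(cols, copy=False))


def _empty_day(pid, stream, date) -> StreamDay:
    return StreamDay(pid, stream, date, empty_records(stream))


def _sleep_segments(onset_ms: int, bed_ms: int, eff: float) -> list[tuple[str, int, int]]:
    """Tile [onset, onset+bed] with staged segments whose asleep total is
    exactly eff% of time in bed."""
    asleep_ms = int(round(bed_ms * eff / 100.0))
    wake_ms = bed_ms - asleep_ms
    # three sleep cycles, wake time split between and at the end of cycles
    cycle = ["light", "deep", "light", "rem"]
    weights = [0.35, 0.25, 0.2, 0.2]
    n_cycles = 3
    seg_plan: list[tuple[str, float]] = []
    for c in range(n_cycles):
        for st, w in zip(cycle, weights):
            seg_plan.append((st, w / n_cycles))
        if c < n_cycles - 1:
            seg_plan.append(("wake", 0.5))  # wake fraction marker
    sleep_units = [(st, f) for st, f in seg_plan if st != "wake"]
    segs: list[tuple[str, int]] = []
    acc = 0
    for k, (st, f) in enumerate(seg_plan):
        if st == "wake":
            d = wake_ms // 2
            segs.append(("wake", d))
            continue
        if (st, f) == sleep_units[-1] and k == len(seg_plan) - 1:
            d = asleep_ms - acc
        else:
            d = int(round(f * asleep_ms))
            acc += d
        segs.append((st, d))
    # ensure exact tiling: absorb rounding into last asleep segment
    total = sum(d for _, d in segs)
    drift = bed_ms - total
    for idx in range(len(segs) - 1, -1, -1):
        if segs[idx][0] != "wake":
            segs[idx] = (segs[idx][0], segs[idx][1] + drift)
            break
    out = []
    t = onset_ms
    for st, d in segs:
        out.append((st, t, t + d))
        t += d
    return out


def generate_participant(
    profile: ParticipantProfile,
    n_days: int,
    effect: RegimeEffect | None,
    miss: MissingnessConfig,
    seed: int,
    start_date: dt.date = dt.date(2020, 2, 22),
    tz_offset_hours: float = 8.0,
    salt: str = "phenokit-study-salt",
) -> ParticipantData:
    """Generate all 13 stream kinds for one participant.

    Same seed => identical output.  Streams whose daily file is planted as
    absent are simply not emitted (the caller records them as missing).
    """
    rng = np.random.default_rng(seed)
    pid = profile.participant_id
    displacement = sample_displacement(pid, seed, lat_hint=profile.home[0])
    epoch0 = dt.datetime(
        start_date.year, start_date.month, start_date.day, tzinfo=dt.timezone.utc
    ).timestamp() * 1000 - tz_offset_hours * 3_600_000
    epoch0 = int(epoch0)
    contacts = [hash_counterparty(f"{pid}-contact-{i:02d}", salt) for i in range(8)]
    key_names = list(KEY_TOKEN_P)
    key_p = np.array([KEY_TOKEN_P[k] for k in key_names])
    key_p = key_p / key_p.sum()

    days: dict[dt.date, dict[str, StreamDay]] = {}

    for d in range(n_days):
        date = start_date + dt.timedelta(days=d)
        day0 = epoch0 + d * DAY_MS
        dow = date.weekday()
        weekend = dow >= 5
        post = effect is not None and d >= effect.changepoint_day
        mult = (lambda k: effect.multipliers.get(k, 1.0)) if post else (lambda k: 1.0)

        silent = rng.random() < miss.p_phone_silent_day
        absent = {
            s: bool(silent or rng.random() < miss.p_file_absent) for s in PHONE_STREAMS
        }
        worn = rng.random() >= miss.p_nonwear_day
        daytime_gap = None
        if worn and rng.random() < miss.p_daytime_nonwear_block:
            g0 = int(rng.integers(540, 1080))
            glen = int(rng.uniform(*miss.nonwear_block_hours) * 60)
            daytime_gap = (g0, g0 + glen)

        out: dict[str, StreamDay] = {}

        # --- sleep episode (wake date = this day) --------------------------
        if worn:
            onset_min = rng.normal(profile.sleep_onset_mean_min, profile.sleep_onset_sd_min)
            dur_h = float(np.clip(
                rng.normal(profile.sleep_duration_mean_h, profile.sleep_duration_sd_h), 3.0, 11.0
            ))
            lo, hi = profile.efficiency_range
            eff = lo + (hi - lo) * rng.beta(2.0, 2.0)
            eff = float(np.clip(eff * mult("sleep_efficiency"), 40.0, 99.5))
            onset_ms = int(day0 - DAY_MS + round(onset_min) * MIN_MS)
            bed_ms = int(round(dur_h * 3600_000))
            segs = _sleep_segments(onset_ms, bed_ms, eff)
            out["sleep"] = _mk_day(pid, "sleep", date, {
                "t": np.array([s for _, s, _ in segs], dtype=np.int64),
                "seg_end": np.array([e for _, _, e in segs], dtype=np.int64),
                "stage": [st for st, _, _ in segs],
                "episode_id": np.zeros(len(segs), dtype=np.int64),
                "episode_start": np.full(len(segs), onset_ms, dtype=np.int64),
                "episode_end": np.full(len(segs), onset_ms + bed_ms, dtype=np.int64),
                "is_main_sleep": np.ones(len(segs), dtype=bool),
            })

        # --- heart (5-min epochs while worn) -------------------------------
        if worn:
            mins = np.arange(0, 1440, 5)
            if daytime_gap is not None:
                mins = mins[(mins < daytime_gap[0]) | (mins >= daytime_gap[1])]
            hour = mins / 60.0
            bpm = (
                profile.hr_baseline * mult("hr")
                + profile.hr_circadian_amp * np.cos(2 * math.pi * (hour - 16.0) / 24.0)
                + rng.normal(0, 2.5, mins.size)
            )
            out["heart"] = _mk_day(pid, "heart", date, {
                "t": day0 + mins.astype(np.int64) * MIN_MS,
                "bpm": np.round(bpm, 1),
                "interval_s": np.full(mins.size, 300.0),
            })

        # --- steps ----------------------------------------------------------
        if worn:
            med = profile.steps_daily_median * mult("steps")
            if weekend:
                med *= profile.steps_weekend_multiplier
            total = (int(round(rng.lognormal(math.log(med), profile.steps_sigma)))
                     if med > 0 else 0)
            walk = min(int(math.floor(total / 125.0)), 800)  # 100-step walk minutes
            rem = total - 100 * walk
            nb = min(rem // 5, 840 - walk - 1)
            leftover = rem - 5 * nb
            n_min = walk + nb + (1 if leftover > 0 else 0)
            mins = np.sort(rng.choice(np.arange(480, 1320), size=n_min, replace=False))
            counts = np.concatenate([
                np.full(walk, 100, dtype=np.int64),
                np.full(nb, 5, dtype=np.int64),
                np.full(1 if leftover > 0 else 0, leftover, dtype=np.int64),
            ])
            if leftover > 9:  # fold tail overflow into a walk minute
                counts[-1] = 9
                if walk:
                    counts[0] += leftover - 9
            out["steps"] = _mk_day(pid, "steps", date, {
                "t": day0 + mins.astype(np.int64) * MIN_MS,
                "n_steps": counts,  # counts are exchangeable across minutes
                "interval_s": np.full(n_min, 60.0),
            })

        # --- gps -------------------------------------------------------------
        if not absent["gps"]:
            mins = np.arange(0, 1440, 10)
            lat = np.full(mins.size, profile.home[0])
            lon = np.full(mins.size, profile.home[1])
            for pl in profile.places:
                if rng.random() < pl.p_visit * mult("away_prob"):
                    m = (mins >= pl.start_min) & (mins < pl.start_min + pl.dur_min)
                    lat[m] = pl.lat
                    lon[m] = pl.lon
            jitter = 8.0 * DEG_PER_M_LAT
            lat = lat + rng.normal(0, jitter, mins.size)
            lon = lon + rng.normal(0, jitter, mins.size)
            gps = pd.DataFrame({
                "t": day0 + mins.astype(np.int64) * MIN_MS,
                "lat": lat,
                "lon": lon,
                "accuracy_m": np.round(rng.uniform(5, 25, mins.size), 1),
            })
            out["gps"] = StreamDay(pid, "gps", date,
                                   obfuscate_gps(gps, displacement).reset_index(drop=True))

        # --- communication logs ---------------------------------------------
        def _comm_times(n):
            return day0 + np.sort(rng.integers(480 * MIN_MS, 1380 * MIN_MS, n))

        def _calls(stream, channel, lam_in, lam_out, lam_missed):
            rows = []
            for direction, lam in (("incoming", lam_in), ("outgoing", lam_out),
                                   ("missed", lam_missed)):
                n = rng.poisson(lam)
                dur = rng.exponential(150.0, n) if direction != "missed" else np.zeros(n)
                for t, ds in zip(_comm_times(n), dur):
                    rows.append((int(t), channel, direction,
                                 contacts[int(rng.integers(0, len(contacts)))],
                                 round(float(ds), 1)))
            if not absent[stream]:
                if rows:
                    out[stream] = _mk_day(pid, stream, date, {
                        "t": np.array([r[0] for r in rows], dtype=np.int64),
                        "channel": [r[1] for r in rows],
                        "direction": [r[2] for r in rows],
                        "counterparty": [r[3] for r in rows],
                        "duration_s": np.array([r[4] for r in rows], dtype=float),
                    })
                else:
                    out[stream] = _empty_day(pid, stream, date)

        def _msgs(stream, channel, lam_in, lam_out):
            rows = []
            for direction, lam in (("incoming", lam_in), ("outgoing", lam_out)):
                n = rng.poisson(lam)
                length = 1 + rng.poisson(30.0, n)
                for t, lc in zip(_comm_times(n), length):
                    rows.append((int(t), channel, direction,
                                 contacts[int(rng.integers(0, len(contacts)))], int(lc)))
            if not absent[stream]:
                if rows:
                    out[stream] = _mk_day(pid, stream, date, {
                        "t": np.array([r[0] for r in rows], dtype=np.int64),
                        "channel": [r[1] for r in rows],
                        "direction": [r[2] for r in rows],
                        "counterparty": [r[3] for r in rows],
                        "length_chars": np.array([r[4] for r in rows], dtype=np.int64),
                    })
                else:
                    out[stream] = _empty_day(pid, stream, date)

        cr = profile.comm_rates
        _calls("call_log", "call",
               cr["call_in"] * mult("incoming_calls"), cr["call_out"], cr["call_missed"])
        _msgs("sms_log", "sms", cr["sms_in"], cr["sms_out"])
        _calls("sociability_call_log", "app_call",
               cr["app_call_in"], cr["app_call_out"], 0.0)
        _msgs("sociability_msg_log", "app_msg", cr["app_msg_in"], cr["app_msg_out"])

        # --- taps -------------------------------------------------------------
        tap_t, tap_app, tap_key = [], [], []
        for cls, lam in profile.taps_rates.items():
            if cls == "entertainment":
                lam = lam * mult("taps_entertainment")
            n = rng.poisson(lam)
            if n == 0:
                continue
            pool = _APP_POOLS[cls]
            k = max(1, int(round(len(pool) * mult("unique_apps"))))
            idx = rng.integers(0, k, n)
            tap_t.append(day0 + rng.integers(480 * MIN_MS, 1380 * MIN_MS, n))
            tap_app.extend(pool[i] for i in idx)
            tap_key.extend(np.array(key_names)[rng.choice(len(key_names), n, p=key_p)])
        if not absent["taps_log"]:
            if tap_t:
                out["taps_log"] = _mk_day(pid, "taps_log", date, {
                    "t": np.concatenate(tap_t).astype(np.int64),
                    "app_id": tap_app,
                    "key_token": tap_key,
                })
            else:
                out["taps_log"] = _empty_day(pid, "taps_log", date)

        # --- accessibility log ------------------------------------------------
        if not absent["accessibility_log"]:
            n = rng.poisson(25.0)
            if n:
                out["accessibility_log"] = _mk_day(pid, "accessibility_log", date, {
                    "t": day0 + rng.integers(420 * MIN_MS, 1420 * MIN_MS, n).astype(np.int64),
                    "app_id": [_APP_POOLS["social_messenger"][0]] * n,
                    "event_type": list(rng.choice(["notification", "message_view"], n)),
                })
            else:
                out["accessibility_log"] = _empty_day(pid, "accessibility_log", date)

        # --- power state -------------------------------------------------------
        ev_t, ev = [], []
        for h in range(24):
            n = rng.poisson(profile.screen_on_hourly_profile[h] * mult("screen_on"))
            if n == 0:
                continue
            on_ms = day0 + h * 3_600_000 + np.sort(rng.integers(0, 3_600_000, n))
            off_ms = on_ms + rng.integers(10_000, 600_000, n)
            ev_t.extend(on_ms.tolist())
            ev.extend(["screen_on"] * n)
            for o in off_ms:
                if o < day0 + DAY_MS:
                    ev_t.append(int(o))
                    ev.append("screen_off")
        if rng.random() < 0.05:
            ev_t.append(day0 + int(rng.integers(0, DAY_MS)))
            ev.append("power_down")
        if not absent["power_state"]:
            if ev_t:
                out["power_state"] = _mk_day(pid, "power_state", date, {
                    "t": np.array(ev_t, dtype=np.int64), "event": ev,
                })
            else:
                out["power_state"] = _empty_day(pid, "power_state", date)

        # --- ambient light ------------------------------------------------------
        if not absent["ambient_light"]:
            mins = np.arange(0, 1440, 30)
            day_mask = (mins >= 480) & (mins < 1200)
            lux = np.where(
                day_mask,
                rng.lognormal(math.log(profile.light_day_lux * mult("lux_day")), profile.light_sigma, mins.size),
                rng.lognormal(math.log(profile.light_night_lux), profile.light_sigma, mins.size),
            )
            out["ambient_light"] = _mk_day(pid, "ambient_light", date, {
                "t": day0 + mins.astype(np.int64) * MIN_MS,
                "lux": np.round(lux, 2),
            })

        # --- accelerometer (hourly 10 Hz bursts) --------------------------------
        if not absent["accel"]:
            sd_scale = mult("accel_std")
            ts, xs, ys, zs = [], [], [], []
            for h in range(24):
                sd = (profile.accel_day_sd if 8 <= h < 22 else profile.accel_night_sd) * sd_scale
                t0 = day0 + h * 3_600_000 + 30 * MIN_MS
                ts.append(t0 + np.arange(6) * 100)
                xs.append(rng.normal(0, sd / 3, 6))
                ys.append(rng.normal(0, sd / 3, 6))
                zs.append(9.81 + rng.normal(0, sd, 6))
            out["accel"] = _mk_day(pid, "accel", date, {
                "t": np.concatenate(ts).astype(np.int64),
                "x": np.round(np.concatenate(xs), 5),
                "y": np.round(np.concatenate(ys), 5),
                "z": np.round(np.concatenate(zs), 5),
            })

        days[date] = out

    return ParticipantData(profile=profile, displacement=displacement, days=days)


# ---------------------------------------------------------------------------
# Planted truth


def _expected_steps(profile: ParticipantProfile, cfg: CohortConfig, days: list[int],
                    steps_mult: float) -> float:
    """Exact expectation of the daily step total over the given study days."""
    if not days:
        return math.nan
    shape = math.exp(profile.steps_sigma**2 / 2)
    tot = 0.0
    for d in days:
        date = cfg.start_date + dt.timedelta(days=d)
        med = profile.steps_daily_median * steps_mult
        if date.weekday() >= 5:
            med *= profile.steps_weekend_multiplier
        tot += med * shape
    return tot / len(days)


def _hr_gap_correction(amp: float, miss: MissingnessConfig) -> float:
    """Expected shift of the duration-weighted daily HR mean caused by the
    daytime non-wear block clipping part of the circadian waveform.

    Deterministic numeric integration over the block's uniform start minute
    (540..1079) and uniform length; the waveform averages to zero over a full
    day, so only the clipped portion matters."""
    if miss.p_daytime_nonwear_block == 0:
        return 0.0
    grid = np.arange(0, 1440, 5)
    wave = np.cos(2 * math.pi * (grid / 60.0 - 16.0) / 24.0)
    lens = np.linspace(miss.nonwear_block_hours[0], miss.nonwear_block_hours[1], 25) * 60
    shifts = []
    for g0 in range(540, 1080, 4):
        for glen in lens:
            gap = (grid >= g0) & (grid < g0 + glen)
            keep = ~gap
            shifts.append(wave[keep].mean())
    return amp * miss.p_daytime_nonwear_block * float(np.mean(shifts))


def _expected_unique_apps(profile: ParticipantProfile, ent_mult: float, pool_mult: float) -> float:
    tot = 0.0
    for cls, lam in profile.taps_rates.items():
        if cls == "entertainment":
            lam = lam * ent_mult
        k = max(1, round(len(_APP_POOLS[cls]) * pool_mult))
        tot += k * (1.0 - math.exp(-lam / k))
    return tot


def planted_truth(cfg: CohortConfig) -> pd.DataFrame:
    """Closed-form expected daily feature means per participant and regime.

    Rows: participant_id, metric, pre_expected, post_expected, direction
    (sign of post - pre; 0 when the family is unaffected).  Metrics without a
    tractable closed form (the ambient-light hourly-max and accelerometer
    summaries) carry NaN expectations but still declare their planted
    direction.
    """
    eff_mults = cfg.effect.multipliers if cfg.effect else {}
    cp = cfg.effect.changepoint_day if cfg.effect else cfg.n_days
    pre_days = list(range(min(cp, cfg.n_days)))
    post_days = list(range(cp, cfg.n_days))

    def m(k):
        return eff_mults.get(k, 1.0)

    rows = []
    for p in cfg.profiles:
        def add(metric, pre, post, direction=None):
            if direction is None:
                if pre is None or post is None or math.isnan(pre) or math.isnan(post):
                    direction = 0
                else:
                    direction = int(np.sign(post - pre))
            rows.append((p.participant_id, metric,
                         math.nan if pre is None else pre,
                         math.nan if post is None else post, direction))

        s_pre = _expected_steps(p, cfg, pre_days, 1.0)
        s_post = _expected_steps(p, cfg, post_days, m("steps"))
        add("daily_n_steps", s_pre, s_post)
        add("daily_n_mins_walk", max(0.0, 0.008 * s_pre - 0.5),
            max(0.0, 0.008 * s_post - 0.5) if not math.isnan(s_post) else math.nan)

        eff_mean = sum(p.efficiency_range) / 2.0
        add("sleep_total_hrs", p.sleep_duration_mean_h * eff_mean / 100.0,
            p.sleep_duration_mean_h * eff_mean * m("sleep_efficiency") / 100.0)
        add("sleep_mean_efficiency", eff_mean, eff_mean * m("sleep_efficiency"))

        # 10-min grid interval bookkeeping: a visit of dur minutes removes
        # (dur + 10) home minutes and contributes (dur - 10) away minutes
        ht_pre = 1430.0 - sum(pl.p_visit * (pl.dur_min + 10) for pl in p.places)
        ht_post = 1430.0 - sum(pl.p_visit * m("away_prob") * (pl.dur_min + 10) for pl in p.places)
        away_pre = sum(pl.p_visit * (pl.dur_min - 10) for pl in p.places)
        away_post = sum(pl.p_visit * m("away_prob") * (pl.dur_min - 10) for pl in p.places)
        add("hometime_min", ht_pre, ht_post)
        add("time_away_from_home_min", away_pre, away_post)

        hr_corr = _hr_gap_correction(p.hr_circadian_amp, cfg.missingness)
        add("hr_mean", p.hr_baseline + hr_corr, p.hr_baseline * m("hr") + hr_corr,
            direction=int(np.sign(m("hr") - 1.0)))
        add("n_incoming_calls", p.comm_rates["call_in"],
            p.comm_rates["call_in"] * m("incoming_calls"))
        msgs = (p.comm_rates["sms_in"] + p.comm_rates["sms_out"]
                + p.comm_rates["app_msg_in"] + p.comm_rates["app_msg_out"])
        add("n_msgs_exchanged", msgs, msgs)
        scr = sum(p.screen_on_hourly_profile) / 24.0
        add("hourly_n_screen_on", scr, scr * m("screen_on"))
        add("n_taps_in_entertainment", p.taps_rates["entertainment"],
            p.taps_rates["entertainment"] * m("taps_entertainment"))
        add("n_unique_apps", _expected_unique_apps(p, 1.0, 1.0),
            _expected_unique_apps(p, m("taps_entertainment"), m("unique_apps")))

        # direction-only families (no tractable closed form for the mean)
        add("ambient_hourly_max_log1p_lux", None, None,
            int(np.sign(m("lux_day") - 1.0)))
        add("accel_L_std", None, None, int(np.sign(m("accel_std") - 1.0)))
        add("accel_ddt_max", None, None, int(np.sign(m("accel_std") - 1.0)))

    return pd.DataFrame(rows, columns=[
        "participant_id", "metric", "pre_expected", "post_expected", "direction"
    ])


def presence_truth(cfg: CohortConfig) -> pd.DataFrame:
    """Expected per-stream daily file-presence probability."""
    mc = cfg.missingness
    phone_p = (1 - mc.p_phone_silent_day) * (1 - mc.p_file_absent)
    rows = [(s, phone_p) for s in PHONE_STREAMS]
    rows += [(s, 1 - mc.p_nonwear_day) for s in WEARABLE_STREAMS]
    return pd.DataFrame(rows, columns=["stream", "expected_presence"])


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(cfg: CohortConfig, seed: int, out_dir: Path | str | None = None) -> Cohort:
    """Generate the full cohort; per-participant seeds are spawned from the
    master seed.  If ``out_dir`` is given, every present stream-day is written
    as CSV and the truth manifest + missing-day list are saved alongside."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cfg.profiles))
    participants: dict[str, ParticipantData] = {}
    presence_rows = []
    missing_rows = []
    dates = [cfg.start_date + dt.timedelta(days=d) for d in range(cfg.n_days)]

    for profile, child in zip(cfg.profiles, children):
        pseed = int(child.generate_state(1)[0] % (2**31))
        pdata = generate_participant(
            profile, cfg.n_days, cfg.effect, cfg.missingness, pseed,
            start_date=cfg.start_date, tz_offset_hours=cfg.tz_offset_hours, salt=cfg.salt,
        )
        participants[profile.participant_id] = pdata
        for date in dates:
            present = pdata.days.get(date, {})
            for s in ALL_STREAMS:
                ok = s in present
                presence_rows.append((profile.participant_id, date, s, ok))
                if not ok:
                    missing_rows.append((profile.participant_id, date, s))

    cohort = Cohort(
        config=cfg,
        seed=seed,
        participants=participants,
        manifest=planted_truth(cfg),
        presence=pd.DataFrame(presence_rows,
                              columns=["participant_id", "date", "stream", "file_present"]),
        missing_days=pd.DataFrame(missing_rows, columns=["participant_id", "date", "stream"]),
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: Path | str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pdata in cohort.participants.values():
        for date in sorted(pdata.days):
            for s in sorted(pdata.days[date]):
                write_stream_day(pdata.days[date][s], out_dir)
    cohort.manifest.to_csv(out_dir / "truth_manifest.csv", index=False)
    cohort.missing_days.to_csv(out_dir / "missing_stream_days.csv", index=False)
    enrollment = pd.DataFrame({
        "participant_id": [p for p in cohort.participants],
        "start_date": cohort.config.start_date.isoformat(),
        "end_date": (cohort.config.start_date
                     + dt.timedelta(days=cohort.config.n_days - 1)).isoformat(),
    })
    enrollment.to_csv(out_dir / "enrollment.csv", index=False)
    return out_dir
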