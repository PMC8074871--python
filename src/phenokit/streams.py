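"""On-disk data model for raw sensor streams and at-collection privacy transforms.

Layout: one UTF-8 CSV per participant / stream / local calendar date at
``<root>/<participant>/<stream>/<YYYY-MM-DD>.csv``.  The first column is
always an ISO-8601 UTC timestamp with millisecond precision; the remaining
columns are stream specific (see :data:`SCHEMAS`).  A header-only file is a
meaningful observation: it says the stream was collected that day but no
events occurred, which is distinct from the file being absent.

Privacy transforms applied at "collection" time (i.e. before anything is
written): GPS coordinates are displaced by a per-participant random offset,
communication counterparties are replaced by keyed hash tokens, and raw
keystrokes are reduced to type tokens.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import hmac
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Stream registry

PHONE_STREAMS = (
    "accel",
    "gps",
    "power_state",
    "call_log",
    "sms_log",
    "sociability_call_log",
    "sociability_msg_log",
    "taps_log",
    "accessibility_log",
    "ambient_light",
)
WEARABLE_STREAMS = ("heart", "steps", "sleep")
ALL_STREAMS = PHONE_STREAMS + WEARABLE_STREAMS

# Column kinds drive parsing/formatting: "ts" = epoch-ms stored as ISO-8601,
# "float", "int", "str", "bool".  The timestamp column "t" is implicit and
# always first (written as "timestamp").
SCHEMAS: dict[str, dict[str, str]] = {
    "accel": {"x": "float", "y": "float", "z": "float"},
    "gps": {"lat": "float", "lon": "float", "accuracy_m": "ofloat"},
    "power_state": {"event": "str"},
    "call_log": {
        "channel": "str",
        "direction": "str",
        "counterparty": "str",
        "duration_s": "float",
    },
    "sms_log": {
        "channel": "str",
        "direction": "str",
        "counterparty": "str",
        "length_chars": "int",
    },
    "taps_log": {"app_id": "str", "key_token": "str"},
    "accessibility_log": {"app_id": "str", "event_type": "str"},
    "ambient_light": {"lux": "float"},
    "heart": {"bpm": "float", "interval_s": "float"},
    "steps": {"n_steps": "int", "interval_s": "float"},
    "sleep": {
        "seg_end": "ts",
        "stage": "str",
        "episode_id": "int",
        "episode_start": "ts",
        "episode_end": "ts",
        "is_main_sleep": "bool",
    },
}
SCHEMAS["sociability_call_log"] = dict(SCHEMAS["call_log"])
SCHEMAS["sociability_msg_log"] = dict(SCHEMAS["sms_log"])

POWER_EVENTS = ("screen_on", "screen_off", "power_down")
COMM_CHANNELS = ("call", "sms", "app_call", "app_msg")
COMM_DIRECTIONS = ("incoming", "outgoing", "missed")
KEY_TOKENS = ("alphabetic", "numeric", "punctuation", "delete", "backspace", "enter", "none")
SLEEP_STAGES = ("wake", "light", "deep", "rem", "asleep", "restless")

APP_CLASSES = (
    "social_messenger",
    "social_media",
    "entertainment",
    "map_navigation",
    "utility_tools",
    "games",
    "android_systems",
)

#: per-stream declared column list, timestamp first
def columns_for(stream: str) -> list[str]:
    return ["timestamp", *SCHEMAS[stream].keys()]


@dataclass
class StreamDay:
    """One participant x local-date x stream bundle of records.

    ``records`` is a DataFrame whose first column ``t`` holds UTC epoch
    milliseconds; remaining columns follow :data:`SCHEMAS`.  ``file_present``
    distinguishes "collected but empty" from "not collected at all".
    """

    participant_id: str
    stream: str
    date: dt.date
    records: pd.DataFrame
    file_present: bool = True
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.stream not in SCHEMAS:
            raise ValueError(f"unknown stream {self.stream!r}")
        if self.records is None:
            self.records = empty_records(self.stream)
        if len(self.records) and not self.file_present:
            raise ValueError("records nonempty but file_present is False")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:  # value semantics, incl. frame
        if not isinstance(other, StreamDay):
            return NotImplemented
        if (
            self.participant_id != other.participant_id
            or self.stream != other.stream
            or self.date != other.date
            or self.file_present != other.file_present
        ):
            return False
        a, b = self.records, other.records
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            av, bv = a[c].to_numpy(), b[c].to_numpy()
            if av.dtype.kind == "f":
                if not np.array_equal(av, bv, equal_nan=True):
                    return False
            elif not np.array_equal(av, bv):
                return False
        return True


def empty_records(stream: str) -> pd.DataFrame:
    cols = {"t": pd.Series(dtype="int64")}
    for name, kind in SCHEMAS[stream].items():
        if kind in ("float", "ofloat"):
            dtype = "float64"
        elif kind in ("int", "ts"):
            dtype = "int64"
        elif kind == "bool":
            dtype = "bool"
        else:
            dtype = "object"
        cols[name] = pd.Series(dtype=dtype)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Timestamp helpers


def ms_to_iso(ms: int) -> str:
    """Integer epoch milliseconds -> ISO-8601 UTC string with ms precision."""
    whole = dt.datetime.fromtimestamp(ms // 1000, tz=dt.timezone.utc)
    return f"{whole:%Y-%m-%dT%H:%M:%S}.{ms % 1000:03d}Z"


# ---------------------------------------------------------------------------
# Reading / writing

class FormatError(ValueError):
    """Raised when a stream file's header does not match its declared schema."""


def stream_day_path(root: Path | str, participant_id: str, stream: str, date: dt.date) -> Path:
    return Path(root) / participant_id / stream / f"{date.isoformat()}.csv"


def read_stream_day(
    path: Path | str,
    stream: str,
    participant_id: str | None = None,
    date: dt.date | None = None,
) -> StreamDay:
    """Read one per-day CSV into a :class:`StreamDay`.

    Malformed rows are skipped and counted in ``n_rejected`` (never silently
    dropped); a wrong header raises :class:`FormatError`.  A header-only file
    yields zero records with ``file_present=True``.
    """
    path = Path(path)
    if participant_id is None:
        participant_id = path.parent.parent.name
    if date is None:
        date = dt.date.fromisoformat(path.stem)
    expected = columns_for(stream)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise FormatError(f"{path}: empty file, expected header {expected}") from exc
        if header != expected:
            raise FormatError(f"{path}: header {header} != expected {expected}")
        rows = list(reader)

    ncol = len(expected)
    good = [r for r in rows if len(r) == ncol]
    n_rejected = len(rows) - len(good)
    if not good:
        return StreamDay(participant_id, stream, date, empty_records(stream), True, n_rejected)

    raw = pd.DataFrame(good, columns=expected)
    out: dict[str, pd.Series] = {}
    bad = np.zeros(len(raw), dtype=bool)

    ts = pd.to_datetime(raw["timestamp"], format="%Y-%m-%dT%H:%M:%S.%fZ", errors="coerce", utc=True)
    bad |= ts.isna().to_numpy()
    out["t"] = ts

    for name, kind in SCHEMAS[stream].items():
        col = raw[name]
        if kind == "ts":
            v = pd.to_datetime(col, format="%Y-%m-%dT%H:%M:%S.%fZ", errors="coerce", utc=True)
            bad |= v.isna().to_numpy()
            out[name] = v
        elif kind in ("float", "ofloat"):
            # element-wise float() for correctly-rounded IEEE round trips
            vals = np.empty(len(col))
            badf = np.zeros(len(col), dtype=bool)
            for i, s in enumerate(col.to_numpy()):
                if s == "":
                    vals[i] = np.nan
                    badf[i] = kind != "ofloat"
                else:
                    try:
                        vals[i] = float(s)
                    except ValueError:
                        vals[i] = np.nan
                        badf[i] = True
            bad |= badf
            out[name] = pd.Series(vals)
        elif kind == "int":
            v = pd.to_numeric(col.replace("", np.nan), errors="coerce")
            bad |= v.isna().to_numpy()
            out[name] = v
        elif kind == "bool":
            ok = col.isin(["true", "false"])
            bad |= ~ok.to_numpy()
            out[name] = col == "true"
        else:
            out[name] = col

    df = pd.DataFrame(out)
    n_rejected += int(bad.sum())
    df = df[~bad]
    # finalize dtypes
    df["t"] = (df["t"].astype("int64") // 10**6).astype("int64")
    for name, kind in SCHEMAS[stream].items():
        if kind == "ts":
            df[name] = (df[name].astype("int64") // 10**6).astype("int64")
        elif kind == "int":
            df[name] = df[name].astype("int64")
        elif kind in ("float", "ofloat"):
            df[name] = df[name].astype("float64")
    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    if df.empty:
        df = empty_records(stream)
    return StreamDay(participant_id, stream, date, df, True, n_rejected)


def _format_value(v, kind: str) -> str:
    if kind == "ts":
        return ms_to_iso(int(v))
    if kind in ("float", "ofloat"):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        return repr(float(v))
    if kind == "int":
        return str(int(v))
    if kind == "bool":
        return "true" if v else "false"
    return str(v)


def write_stream_day(day: StreamDay, root: Path | str) -> Path:
    """Write a StreamDay as CSV; inverse of :func:`read_stream_day`.

    Deterministic: two writes of the same day are byte identical.
    """
    path = stream_day_path(root, day.participant_id, day.stream, day.date)
    path.parent.mkdir(parents=True, exist_ok=True)
    schema = SCHEMAS[day.stream]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(columns_for(day.stream))
        if len(day.records):
            cols = [day.records["t"].to_numpy()] + [
                day.records[name].to_numpy() for name in schema
            ]
            kinds = ["ts"] + list(schema.values())
            for row in zip(*cols):
                w.writerow([_format_value(v, k) for v, k in zip(row, kinds)])
    return path


def scan_dataset(root: Path | str):
    """Yield (participant_id, stream, date, path) for every stream-day file."""
    root = Path(root)
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        for sdir in sorted(s for s in pdir.iterdir() if s.is_dir()):
            if sdir.name not in SCHEMAS:
                logging.getLogger(__name__).warning(
                    "ignoring unknown stream directory %s", sdir)
                continue
            for f in sorted(sdir.glob("*.csv")):
                yield pdir.name, sdir.name, dt.date.fromisoformat(f.stem), f


# ---------------------------------------------------------------------------
# Privacy transforms

EARTH_RADIUS_M = 6_371_000.0
DEFAULT_REF_LAT = 1.35  # Singapore; fixes the equirectangular E-W scale


def planar_distance_m(lat1, lon1, lat2, lon2, ref_lat: float = DEFAULT_REF_LAT):
    """Equirectangular planar distance in meters.

    The east-west scale uses the cosine of a fixed study reference latitude,
    so the metric depends only on coordinate differences and is exactly
    invariant under the per-participant obfuscation translation.  Adequate at
    city scale (the study setting); not for continental distances.
    """
    k = math.pi / 180.0
    dy = (np.asarray(lat2) - np.asarray(lat1)) * k
    dx = (np.asarray(lon2) - np.asarray(lon1)) * k * math.cos(ref_lat * k)
    return EARTH_RADIUS_M * np.hypot(dx, dy)


def sample_displacement(
    participant_id: str, seed: int, max_deg: float = 1.0, lat_hint: float = DEFAULT_REF_LAT
) -> tuple[float, float]:
    """Draw the per-participant GPS displacement (dlat, dlon) in degrees.

    Deterministic in (participant_id, seed); resampled if the displaced
    latitude could leave [-90, 90].
    """
    digest = hashlib.sha256(f"{seed}:{participant_id}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
    while True:
        dlat = float(rng.uniform(-max_deg, max_deg))
        dlon = float(rng.uniform(-max_deg, max_deg))
        if -90.0 <= lat_hint + dlat <= 90.0:
            return dlat, dlon


def obfuscate_gps(records: pd.DataFrame, displacement: tuple[float, float]) -> pd.DataFrame:
    """Apply the participant's fixed random displacement to GPS records.

    Pure translation in (lat, lon) degrees: pairwise planar distances are
    preserved exactly.
    """
    dlat, dlon = displacement
    out = records.copy()
    out["lat"] = out["lat"] + dlat
    out["lon"] = out["lon"] + dlon
    if (out["lat"].abs() > 90).any():
        raise ValueError("displacement pushes latitude outside [-90, 90]")
    return out


_DIGITS_ONLY = re.compile(r"^\+?\d+$")
EMPTY_COUNTERPARTY_TOKEN = "h-anonymous"


def looks_like_raw_number(token: str) -> bool:
    return bool(_DIGITS_ONLY.match(token))


def hash_counterparty(raw_id: str, salt: str) -> str:
    """Keyed one-way hash of a counterparty identity.

    HMAC-SHA256 truncated to 128 bits, prefixed with ``h-`` so the token can
    never pass a digits-only phone-number pattern check.  Empty identities map
    to a designated sentinel token.
    """
    if raw_id == "":
        return EMPTY_COUNTERPARTY_TOKEN
    mac = hmac.new(salt.encode("utf-8"), raw_id.encode("utf-8"), hashlib.sha256)
    return "h-" + mac.hexdigest()[:32]


_PUNCT = set("!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~")
_KEY_ALIASES = {
    "del": "delete", "delete": "delete",
    "bksp": "backspace", "backspace": "backspace",
    "enter": "enter", "return": "enter",
}


def tokenize_key(raw_key: str) -> str:
    """Reduce a raw key descriptor to a privacy-preserving type token.

    Total function: anything unrecognized (including navigation taps) maps to
    ``none``.
    """
    k = raw_key.strip()
    low = k.lower()
    if low in _KEY_ALIASES:
        return _KEY_ALIASES[low]
    if len(k) == 1:
        if k.isalpha():
            return "alphabetic"
        if k.isdigit():
            return "numeric"
        if k in _PUNCT:
            return "punctuation"
    return "none"


# ---------------------------------------------------------------------------
# App grouper

def load_app_mapping(path: Path | str | None = None) -> dict[str, str]:
    """Load the two-column TSV app -> class mapping (default: shipped table)."""
    if path is None:
        path = Path(__file__).parent / "data" / "app_classes.tsv"
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            app, cls = line.split("\t")
            if cls not in APP_CLASSES:
                raise ValueError(f"unknown app class {cls!r} for {app!r}")
            mapping[app] = cls
    return mapping


def classify_app(app_id: str, mapping: dict[str, str]) -> str:
    """Map an app id to one of the 7 behavioral classes.

    Apps absent from the mapping (vendor/system apps not in the store) fall
    into ``android_systems``.
    """
    return mapping.get(app_id, "android_systems")
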