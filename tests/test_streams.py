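"""Stream I/O round trips, presence semantics, and privacy transforms."""

import datetime as dt
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenokit.streams as ps
from phenokit.streams import (
    ALL_STREAMS,
    StreamDay,
    empty_records,
    hash_counterparty,
    load_app_mapping,
    classify_app,
    obfuscate_gps,
    planar_distance_m,
    read_stream_day,
    sample_displacement,
    tokenize_key,
    write_stream_day,
)

from conftest import mk_day

DATE = dt.date(2020, 4, 1)


# ---------------------------------------------------------------------------
# Round trip


def test_round_trip_all_streams(full_stream_participant, tmp_path):
    """write -> read is the identity on every one of the 13 stream kinds."""
    seen = set()
    for date, streams in full_stream_participant.days.items():
        for name, day in streams.items():
            path = write_stream_day(day, tmp_path)
            back = read_stream_day(path, name)
            assert back == day, f"round trip failed for {name} {date}"
            assert back.n_rejected == 0
            seen.add(name)
    assert seen == set(ALL_STREAMS)


def test_empty_day_round_trips_as_header_only(tmp_path):
    day = StreamDay("P9", "call_log", DATE, empty_records("call_log"))
    path = write_stream_day(day, tmp_path)
    text = path.read_text()
    assert text.strip().count("\n") == 0  # header only
    back = read_stream_day(path, "call_log")
    assert back.file_present and back.n_records == 0
    assert back == day


def test_two_writes_are_byte_identical(full_stream_participant, tmp_path):
    date = min(full_stream_participant.days)
    day = full_stream_participant.days[date]["gps"]
    p1 = write_stream_day(day, tmp_path / "a")
    p2 = write_stream_day(day, tmp_path / "b")
    assert p1.read_bytes() == p2.read_bytes()


@settings(max_examples=25, deadline=None)
@given(
    rows=st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=2**40),
            st.floats(allow_nan=False, allow_infinity=False, width=64),
            st.floats(allow_nan=False, allow_infinity=False, width=64),
            st.floats(allow_nan=False, allow_infinity=False, width=64),
        ),
        max_size=30,
    )
)
def test_accel_round_trip_property(tmp_path_factory, rows):
    """Arbitrary finite accelerometer records survive the CSV round trip."""
    tmp = tmp_path_factory.mktemp("rt")
    day = mk_day(
        "accel",
        t=np.array(sorted(r[0] for r in rows), dtype=np.int64),
        x=np.array([r[1] for r in rows]),
        y=np.array([r[2] for r in rows]),
        z=np.array([r[3] for r in rows]),
    )
    back = read_stream_day(write_stream_day(day, tmp), "accel")
    assert back == day


def test_out_of_order_rows_sorted_on_read(tmp_path):
    p = tmp_path / "P1" / "accel"
    p.mkdir(parents=True)
    f = p / "2020-04-01.csv"
    f.write_text(
        "timestamp,x,y,z\n"
        "2020-04-01T03:00:00.000Z,0.0,0.0,9.81\n"
        "2020-04-01T01:00:00.000Z,0.1,0.0,9.81\n"
        "2020-04-01T02:00:00.000Z,0.2,0.0,9.81\n"
    )
    day = read_stream_day(f, "accel")
    assert day.n_records == 3
    assert list(day.records["t"]) == sorted(day.records["t"])


def test_malformed_rows_rejected_and_counted(tmp_path):
    p = tmp_path / "P1" / "ambient_light"
    p.mkdir(parents=True)
    f = p / "2020-04-01.csv"
    f.write_text(
        "timestamp,lux\n"
        "2020-04-01T01:00:00.000Z,5.0\n"
        "not-a-timestamp,5.0\n"
        "2020-04-01T02:00:00.000Z,not-a-number\n"
        "2020-04-01T03:00:00.000Z\n"          # wrong field count
        "2020-04-01T04:00:00.000Z,7.5\n"
    )
    day = read_stream_day(f, "ambient_light")
    # accounting identity: rows in file == parsed + rejected
    assert day.n_records == 2
    assert day.n_rejected == 3
    assert day.n_records + day.n_rejected == 5


def test_wrong_header_is_a_format_error(tmp_path):
    p = tmp_path / "P1" / "gps"
    p.mkdir(parents=True)
    f = p / "2020-04-01.csv"
    f.write_text("timestamp,latitude,longitude\n")
    with pytest.raises(ps.FormatError):
        read_stream_day(f, "gps")


# ---------------------------------------------------------------------------
# GPS obfuscation


def _gps_frame(lat, lon):
    return pd.DataFrame({
        "t": np.arange(len(lat), dtype=np.int64),
        "lat": np.asarray(lat, dtype=float),
        "lon": np.asarray(lon, dtype=float),
        "accuracy_m": np.full(len(lat), 10.0),
    })


def test_obfuscation_preserves_pairwise_distances():
    rng = np.random.default_rng(0)
    lat = 1.3 + rng.uniform(-0.05, 0.05, 40)
    lon = 103.8 + rng.uniform(-0.05, 0.05, 40)
    rec = _gps_frame(lat, lon)
    out = obfuscate_gps(rec, (0.73, -0.41))
    for i in range(0, 40, 7):
        d0 = planar_distance_m(lat[i], lon[i], lat, lon)
        d1 = planar_distance_m(out["lat"][i], out["lon"][i], out["lat"], out["lon"])
        mask = d0 > 0
        assert np.allclose(d1[mask] / d0[mask], 1.0, rtol=0, atol=1e-9)


def test_zero_displacement_is_identity():
    rec = _gps_frame([1.3, 1.31], [103.8, 103.81])
    out = obfuscate_gps(rec, (0.0, 0.0))
    pd.testing.assert_frame_equal(out, rec)


def test_displacement_unique_per_participant_and_stable():
    d1 = sample_displacement("P001", seed=3)
    d2 = sample_displacement("P001", seed=3)
    d3 = sample_displacement("P002", seed=3)
    assert d1 == d2       # same participant, any day: same displacement
    assert d1 != d3       # distinct participants get distinct displacements


def test_displacement_respects_latitude_bounds():
    dlat, _ = sample_displacement("P001", seed=3, max_deg=1.0, lat_hint=89.5)
    assert -90.0 <= 89.5 + dlat <= 90.0


# ---------------------------------------------------------------------------
# Counterparty hashing, key tokens, app classes


def test_hash_counterparty_deterministic_and_salted():
    a = hash_counterparty("81234567", "s1")
    assert a == hash_counterparty("81234567", "s1")
    assert a != hash_counterparty("81234567", "s2")
    assert "81234567" not in a
    assert not ps.looks_like_raw_number(a)


def test_hash_counterparty_empty_sentinel():
    assert hash_counterparty("", "s") == ps.EMPTY_COUNTERPARTY_TOKEN


@pytest.mark.parametrize("raw,expected", [
    ("a", "alphabetic"), ("Z", "alphabetic"),
    ("7", "numeric"), ("0", "numeric"),
    (".", "punctuation"), ("?", "punctuation"),
    ("BKSP", "backspace"), ("backspace", "backspace"),
    ("DEL", "delete"), ("ENTER", "enter"), ("RETURN", "enter"),
    ("NAV_TAP", "none"), ("", "none"), ("ab", "none"),
])
def test_tokenize_key(raw, expected):
    assert tokenize_key(raw) == expected


def test_classify_app_defaults_and_stability():
    mapping = load_app_mapping()
    assert classify_app("com.unknown.vendor.thing", mapping) == "android_systems"
    assert classify_app("sg.app.video", mapping) == "entertainment"
    assert classify_app("sg.app.video", mapping) == "entertainment"  # stable


# ---------------------------------------------------------------------------
# Privacy scan of serialized output


def test_written_files_contain_no_raw_identifiers(full_stream_participant, tmp_path):
    """No digits-only counterparty and no raw keystroke content anywhere in
    the serialized stream files."""
    digits_field = re.compile(r"(^|,)\+?\d{7,}(,|$)")
    for date, streams in full_stream_participant.days.items():
        for name in ("call_log", "sms_log", "sociability_call_log",
                     "sociability_msg_log", "taps_log"):
            if name not in streams:
                continue
            path = write_stream_day(streams[name], tmp_path)
            for line in path.read_text().splitlines()[1:]:
                fields = line.split(",")
                if name == "taps_log":
                    assert fields[2] in ps.KEY_TOKENS
                else:
                    assert not digits_field.search(",".join(fields[3:4]))
                    assert fields[3].startswith("h-")
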