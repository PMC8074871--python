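"""Data-completeness accounting: per-feature completion rates, the
participant x day completion matrix, and upload-status coloring.

A day "has data" for a stream iff its daily file is present — an
empty-but-present file counts as collected, since for event streams a day
with no calls or messages is a legitimate observation.  Rates are pooled
over participant-days per raw feature; the overall aggregate is the
unweighted mean of the per-feature rates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .streams import ALL_STREAMS, PHONE_STREAMS, WEARABLE_STREAMS


def completion_rate(presence: "pd.Series | np.ndarray | list[bool]",
                    enrollment_days: int) -> float:
    """100 x days-with-data / days-enrolled, reported to 1 decimal."""
    if enrollment_days < 1:
        raise ValueError("enrollment_days must be >= 1")
    n_with = int(np.asarray(presence, dtype=bool).sum())
    return round(100.0 * n_with / enrollment_days, 1)


def overall_rate(per_feature_rates) -> float:
    """Unweighted mean of per-feature completion rates, to 1 decimal."""
    rates = np.asarray(list(per_feature_rates), dtype=float)
    if rates.size == 0:
        raise ValueError("no per-feature rates")
    return round(float(rates.mean()), 1)


def completion_report(presence: pd.DataFrame,
                      enrollment_days: dict[str, int] | int | None = None) -> pd.DataFrame:
    """Per-stream pooled completion rates plus an Overall row.

    ``presence`` has columns participant_id, date, stream, file_present (one
    row per enrolled participant-day-stream).  The pooled rate for a stream
    is participant-days with data over participant-days enrolled.
    """
    rows = []
    for stream in ALL_STREAMS:
        sub = presence[presence["stream"] == stream]
        if not len(sub):
            continue
        rows.append({
            "raw_feature": stream,
            "completion_rate_pct": completion_rate(sub["file_present"], len(sub)),
        })
    out = pd.DataFrame(rows)
    out.loc[len(out)] = {
        "raw_feature": "Overall",
        "completion_rate_pct": overall_rate(out["completion_rate_pct"]),
    }
    return out


def reference_completion_table() -> pd.DataFrame:
    """The shipped reference table of per-feature completion rates observed in
    the 22-participant deployment the synthetic defaults emulate."""
    path = Path(__file__).parent / "data" / "reference_completion_rates.csv"
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Completion matrix (phone row + wearable row per participant)

STATUS_COMPLETE = "complete"
STATUS_PARTIAL = "partial"
STATUS_MISSING = "missing"
STATUS_NOT_ENROLLED = "not_enrolled"


def completion_matrix(presence: pd.DataFrame,
                      enrollment: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per participant x day x device-group completion status.

    complete = every stream in the group present that day; partial = some;
    missing = none; not_enrolled outside the enrollment window.
    """
    groups = {"phone": set(PHONE_STREAMS), "wearable": set(WEARABLE_STREAMS)}
    windows = {}
    if enrollment is not None:
        for _, r in enrollment.iterrows():
            windows[r["participant_id"]] = (
                dt.date.fromisoformat(str(r["start_date"])),
                dt.date.fromisoformat(str(r["end_date"])),
            )
    rows = []
    for (pid, date), sub in presence.groupby(["participant_id", "date"], sort=True):
        win = windows.get(pid)
        for gname, gstreams in groups.items():
            if win is not None and not (win[0] <= date <= win[1]):
                status = STATUS_NOT_ENROLLED
            else:
                present = sub[sub["stream"].isin(gstreams)]["file_present"]
                n = int(present.sum())
                if n == len(gstreams):
                    status = STATUS_COMPLETE
                elif n > 0:
                    status = STATUS_PARTIAL
                else:
                    status = STATUS_MISSING
            rows.append({"participant_id": pid, "date": date,
                         "device_group": gname, "status": status})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Upload status colors


@dataclass
class UploadStatus:
    participant_id: str
    stream: str
    hours_since_last_data: float
    color: str  # green = normal, orange = monitor closely, red = act


def upload_status(
    last_data_time: dt.datetime,
    now: dt.datetime,
    participant_id: str = "",
    stream: str = "",
    green_max_h: float = 24.0,
    red_min_h: float = 48.0,
) -> UploadStatus:
    """Color-code data-collection recency: green if the last data is at most
    ``green_max_h`` old, red beyond ``red_min_h``, orange in between."""
    if green_max_h >= red_min_h:
        raise ValueError("green_max_h must be < red_min_h")
    delta_h = (now - last_data_time).total_seconds() / 3600.0
    if delta_h < 0:
        raise ValueError("last_data_time lies in the future")
    if delta_h <= green_max_h:
        color = "green"
    elif delta_h <= red_min_h:
        color = "orange"
    else:
        color = "red"
    return UploadStatus(participant_id, stream, delta_h, color)
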