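"""Static HTML/CSV renderings of the monitoring dashboards and the pipeline
driver that chains every stage.

All numeric content in the HTML artifacts is identical to the CSV outputs;
the HTML is a plain-string rendering (tables with colored cells), suitable
for opening from disk.  Nothing personally identifying is ever logged or
rendered — streams are already tokenized/obfuscated upstream.
"""

from __future__ import annotations

import datetime as dt
import html
import logging
import math
from pathlib import Path

import pandas as pd

from . import anomaly as anom
from . import compare as cmp_mod
from . import completeness as compl
from .config import PipelineConfig
from .features import DISPLAY_NAMES, build_daily_table

log = logging.getLogger(__name__)

_CSS = """
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 3px 8px; text-align: right; }
th { background: #eee; }
.green { background: #b7e1a1; } .orange { background: #ffd27f; }
.red { background: #ff9d9d; } .gray { background: #ddd; }
.complete { background: #b7e1a1; } .partial { background: #ffd27f; }
.missing { background: #ff9d9d; } .not_enrolled { background: #ddd; }
"""


def _page(title: str, body: str) -> str:
    return (f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{html.escape(title)}</title><style>{_CSS}</style></head>"
            f"<body><h1>{html.escape(title)}</h1>{body}</body></html>")


def _table(df: pd.DataFrame, cell_class=None, float_fmt="{:.4g}") -> str:
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in df.columns)
    rows = []
    for _, r in df.iterrows():
        cells = []
        for c in df.columns:
            v = r[c]
            txt = (float_fmt.format(v) if isinstance(v, float) and math.isfinite(v)
                   else "" if isinstance(v, float) and math.isnan(v) else str(v))
            cls = cell_class(c, v) if cell_class else None
            cells.append(f"<td class='{cls}'>{html.escape(txt)}</td>" if cls
                         else f"<td>{html.escape(txt)}</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    return f"<table><tr>{head}</tr>{''.join(rows)}</table>"


def alert_table_html(scores: pd.DataFrame, orange: float = 0.80, red: float = 0.95) -> str:
    """Anomaly dashboard: one row per participant, colored by severity.

    Sentinel (unscored) cells are gray, never colored as alerts.
    """
    def cell_class(col, v):
        if col in ("participant_id", "last_update_date"):
            return None
        if not isinstance(v, float) or math.isnan(v):
            return "gray"
        if v >= red:
            return "red"
        if v >= orange:
            return "orange"
        return "green"

    return _page("Anomaly detection dashboard",
                 _table(scores, cell_class, float_fmt="{:.3f}"))


def completion_report_html(report: pd.DataFrame) -> str:
    return _page("Data completion rates", _table(report, float_fmt="{:.1f}"))


def completion_matrix_html(matrix: pd.DataFrame) -> str:
    body = []
    for pid, sub in matrix.groupby("participant_id", sort=True):
        wide = sub.pivot(index="device_group", columns="date", values="status")
        wide = wide.reindex(["phone", "wearable"])
        cells = []
        for g, row in wide.iterrows():
            tds = "".join(f"<td class='{v}' title='{d}'></td>"
                          for d, v in row.items())
            cells.append(f"<tr><th>{html.escape(str(pid))} {g}</th>{tds}</tr>")
        body.append("".join(cells))
    return _page("Data completion overview",
                 "<table>" + "".join(body) + "</table>")


def upload_status_html(statuses) -> str:
    df = pd.DataFrame([s.__dict__ for s in statuses])

    def cell_class(col, v):
        return v if col == "color" else None

    return _page("Data collection dashboard", _table(df, cell_class, "{:.1f}"))


# ---------------------------------------------------------------------------
# Clinician summary windows


CLINICIAN_FEATURES = [
    "sleep_total_hrs", "sleep_mean_efficiency", "n_msgs_exchanged",
    "n_calls_gt_1min", "time_away_from_home_min", "radius_of_gyration_m",
]


def clinician_windows(daily: pd.DataFrame, as_of: dt.date,
                      features: list[str] | None = None) -> pd.DataFrame:
    """Per-participant averages over three disjoint look-back windows.

    Counting back from local midnight of ``as_of``: the current week is the 7
    days immediately before, the past week the 7 days before that, and the
    past month the 30 days before the past week (days 15-44 back).  Windows
    with no non-missing days yield NaN cells.
    """
    features = features or [f for f in CLINICIAN_FEATURES if f in daily.columns]
    days_back = (pd.Timestamp(as_of) - pd.to_datetime(daily["date"])).dt.days
    windows = {
        "current_week": days_back.between(1, 7),
        "past_week": days_back.between(8, 14),
        "past_month": days_back.between(15, 44),
    }
    rows = []
    for pid, idx in daily.groupby("participant_id", sort=True).groups.items():
        for wname, mask in windows.items():
            sel = daily.loc[idx][mask.loc[idx]]
            row = {"participant_id": pid, "window": wname}
            for f in features:
                row[f] = float(sel[f].mean()) if len(sel) else math.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline driver


def run_pipeline(config: PipelineConfig, dataset_root: Path | str,
                 out_dir: Path | str) -> dict[str, Path]:
    """Chain extract -> completeness -> anomaly -> compare and emit a static
    report bundle.  Idempotent: identical inputs produce identical outputs."""
    dataset_root = Path(dataset_root)
    out_dir = Path(out_dir)
    if not dataset_root.is_dir() or not any(dataset_root.iterdir()):
        raise FileNotFoundError(f"dataset root {dataset_root} is missing or empty")
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    enrollment = None
    enr_path = (Path(config.enrollment_path) if config.enrollment_path
                else dataset_root / "enrollment.csv")
    if enr_path.exists():
        enrollment = pd.read_csv(enr_path)

    log.info("stage extract: reading %s", dataset_root)
    fcfg = config.feature_config()
    daily = build_daily_table(dataset_root, fcfg, enrollment=enrollment)
    features_csv = out_dir / "features.csv"
    daily.to_csv(features_csv, index=False)
    outputs["features"] = features_csv
    log.info("stage extract: %d participant-days", len(daily))

    # completeness over the same dataset
    presence = _presence_from_disk(dataset_root, enrollment)
    report = compl.completion_report(presence)
    report.to_csv(out_dir / "completion_rates.csv", index=False)
    (out_dir / "completion_rates.html").write_text(
        completion_report_html(report), encoding="utf-8")
    matrix = compl.completion_matrix(presence, enrollment)
    matrix.to_csv(out_dir / "completion_matrix.csv", index=False)
    (out_dir / "completion_matrix.html").write_text(
        completion_matrix_html(matrix), encoding="utf-8")
    outputs["completeness"] = out_dir / "completion_rates.csv"
    log.info("stage completeness: %d streams", len(report) - 1)

    feature_cols = [f for f in cmp_mod.DEFAULT_COMPARE_FEATURES if f in daily.columns]
    scores = anom.score_table(daily, feature_cols, config.model_kind, config.min_history)
    scores.to_csv(out_dir / "anomaly_scores.csv", index=False)
    (out_dir / "anomaly_scores.html").write_text(
        alert_table_html(scores, config.alert_orange, config.alert_red),
        encoding="utf-8")
    outputs["anomaly"] = out_dir / "anomaly_scores.csv"
    log.info("stage anomaly: scored %d participants", len(scores))

    if config.event_date:
        event = dt.date.fromisoformat(config.event_date)
        table = cmp_mod.compare_table(
            daily, event, feature_cols,
            tuple(config.before_window), tuple(config.after_window),
            config.min_days_per_window,
        )
        table.insert(1, "display_name",
                     [DISPLAY_NAMES.get(f, f) for f in table["feature"]])
        table.to_csv(out_dir / "comparison.csv", index=False)
        outputs["comparison"] = out_dir / "comparison.csv"
        log.info("stage compare: %d features at %s", len(table), event)

    links = "".join(f"<li><a href='{p.name}'>{k}</a></li>"
                    for k, p in outputs.items())
    (out_dir / "index.html").write_text(
        _page("phenokit report bundle", f"<ul>{links}</ul>"), encoding="utf-8")
    outputs["index"] = out_dir / "index.html"
    return outputs


def _presence_from_disk(root: Path, enrollment: pd.DataFrame | None) -> pd.DataFrame:
    from .streams import ALL_STREAMS, scan_dataset

    seen: dict[tuple, bool] = {}
    pids = set()
    dates = set()
    for pid, stream, date, _ in scan_dataset(root):
        seen[(pid, date, stream)] = True
        pids.add(pid)
        dates.add(date)
    rows = []
    for pid in sorted(pids):
        if enrollment is not None and pid in set(enrollment["participant_id"]):
            r = enrollment[enrollment["participant_id"] == pid].iloc[0]
            start = dt.date.fromisoformat(str(r["start_date"]))
            end = dt.date.fromisoformat(str(r["end_date"]))
            prange = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
        else:
            prange = sorted(dates)
        for date in prange:
            for s in ALL_STREAMS:
                rows.append((pid, date, s, seen.get((pid, date, s), False)))
    return pd.DataFrame(rows, columns=["participant_id", "date", "stream", "file_present"])
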