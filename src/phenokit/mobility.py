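"""Home and significant-location inference from GPS, plus daily mobility metrics.

Clustering is a deterministic greedy chronological density pass: each point
joins the first existing cluster whose anchor lies within ``eps_m``, otherwise
it founds a new cluster anchored at itself.  Clusters whose cumulative dwell
reaches ``min_dwell_min`` are *significant*.  Home is the cluster with the
most nocturnal dwell (the sleeping location).

"Radius of gyration" here follows the clinician-dashboard usage: the maximum
distance traveled from home on a day.  The classical RMS-displacement
definition is available via ``rog_mode="rms"``.

No imputation of GPS gaps is performed anywhere: intervals longer than
``gap_max_min`` contribute to neither hometime nor time away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .streams import StreamDay, planar_distance_m

MS_PER_MIN = 60_000.0


@dataclass
class SigLocation:
    label: int
    center: tuple[float, float]
    radius_m: float
    total_dwell_min: float
    night_dwell_min: float
    is_home: bool = False
    low_confidence: bool = False


def _local_minute(t_ms: np.ndarray, tz_offset_hours: float) -> np.ndarray:
    return ((t_ms + tz_offset_hours * 3_600_000) % 86_400_000) / MS_PER_MIN


def cluster_significant_locations(
    gps_days: list[StreamDay],
    eps_m: float = 100.0,
    min_dwell_min: float = 30.0,
    gap_cap_min: float = 30.0,
    tz_offset_hours: float = 8.0,
    night_window: tuple[float, float] = (0.0, 6.0),
    ref_lat: float | None = None,
) -> list[SigLocation]:
    """Greedy chronological density clustering of a participant's GPS points.

    Dwell credited to a point is the gap to the next point of the same day,
    capped at ``gap_cap_min`` (the last point of a day gets no dwell).
    Deterministic given input order; points are processed in time order.
    """
    if not any(len(d.records) for d in gps_days):
        return []
    parts = []
    for day in sorted((d for d in gps_days if len(d.records)), key=lambda s: s.date):
        r = day.records
        t = r["t"].to_numpy(dtype=np.float64)
        dwell = np.minimum(np.diff(t, append=t[-1]) / MS_PER_MIN, gap_cap_min)
        parts.append(pd.DataFrame({
            "t": t, "lat": r["lat"].to_numpy(), "lon": r["lon"].to_numpy(), "dwell": dwell,
        }))
    pts = pd.concat(parts, ignore_index=True)
    if ref_lat is None:
        ref_lat = float(pts["lat"].iloc[0])

    lat = pts["lat"].to_numpy()
    lon = pts["lon"].to_numpy()
    dwell = pts["dwell"].to_numpy()
    minute = _local_minute(pts["t"].to_numpy(), tz_offset_hours)
    night = (minute >= night_window[0] * 60) & (minute < night_window[1] * 60)

    # scaled planar coordinates so the greedy pass is plain arithmetic
    ky = 6_371_000.0 * math.pi / 180.0
    kx = ky * math.cos(math.radians(ref_lat))
    xs = lon * kx
    ys = lat * ky
    eps2 = eps_m * eps_m
    ax: list[float] = []
    ay: list[float] = []
    assign = np.empty(len(pts), dtype=np.int64)
    for i in range(len(pts)):
        x, y = xs[i], ys[i]
        best, best_d2 = -1, eps2
        for j in range(len(ax)):
            dx = x - ax[j]
            dy = y - ay[j]
            d2 = dx * dx + dy * dy
            if d2 <= best_d2:
                best, best_d2 = j, d2
        if best >= 0:
            assign[i] = best
        else:
            ax.append(x)
            ay.append(y)
            assign[i] = len(ax) - 1
    clusters: list[SigLocation] = []
    for j in range(len(ax)):
        m = assign == j
        tot = float(dwell[m].sum())
        if tot < min_dwell_min:
            continue
        c_lat = float(np.average(lat[m], weights=np.maximum(dwell[m], 1e-9)))
        c_lon = float(np.average(lon[m], weights=np.maximum(dwell[m], 1e-9)))
        rad = float(np.max(planar_distance_m(lat[m], lon[m], c_lat, c_lon, ref_lat=ref_lat)))
        clusters.append(SigLocation(
            label=len(clusters),
            center=(c_lat, c_lon),
            radius_m=max(rad, 1.0),
            total_dwell_min=tot,
            night_dwell_min=float(dwell[m & night].sum()),
        ))
    return clusters


def infer_home(clusters: list[SigLocation]) -> SigLocation:
    """Home = cluster with maximum nocturnal dwell; ties broken by larger
    total dwell, then smallest label.  With zero nocturnal coverage anywhere,
    falls back to maximum total dwell and flags low confidence."""
    if not clusters:
        raise ValueError("no clusters to infer home from")
    for c in clusters:
        c.is_home = False
    if all(c.night_dwell_min == 0 for c in clusters):
        home = max(clusters, key=lambda c: (c.total_dwell_min, -c.label))
        home.low_confidence = True
    else:
        home = max(clusters, key=lambda c: (c.night_dwell_min, c.total_dwell_min, -c.label))
    home.is_home = True
    return home


def daily_mobility(
    gps_day: StreamDay | None,
    home: SigLocation,
    clusters: list[SigLocation],
    home_radius_m: float = 200.0,
    gap_max_min: float = 30.0,
    eps_m: float = 100.0,
    rog_mode: str = "max",
    ref_lat: float | None = None,
) -> dict[str, float]:
    """Daily mobility metrics from one day's GPS trace.

    hometime / time-away sum the durations of inter-sample intervals no longer
    than ``gap_max_min`` whose *both* endpoints are at home / away; mixed or
    long intervals count toward neither, so the two never double-count and
    never exceed the day length.
    """
    if gps_day is None or not len(gps_day.records):
        return {
            "hometime_min": math.nan,
            "time_away_from_home_min": math.nan,
            "sig_locs_visited": math.nan,
            "radius_of_gyration_m": math.nan,
        }
    r = gps_day.records
    lat = r["lat"].to_numpy()
    lon = r["lon"].to_numpy()
    t = r["t"].to_numpy(dtype=np.float64)
    if ref_lat is None:
        ref_lat = home.center[0]
    dist_home = planar_distance_m(lat, lon, home.center[0], home.center[1], ref_lat=ref_lat)
    at_home = dist_home <= home_radius_m
    dt_min = np.diff(t) / MS_PER_MIN
    ok = dt_min <= gap_max_min
    both_home = at_home[:-1] & at_home[1:] & ok
    both_away = (~at_home[:-1]) & (~at_home[1:]) & ok

    visited = 0
    for c in clusters:
        d = planar_distance_m(lat, lon, c.center[0], c.center[1], ref_lat=ref_lat)
        if (d <= eps_m).any():
            visited += 1

    if rog_mode == "rms":
        rog = float(np.sqrt(np.mean(dist_home**2)))
    else:
        rog = float(dist_home.max())
    return {
        "hometime_min": float(dt_min[both_home].sum()),
        "time_away_from_home_min": float(dt_min[both_away].sum()),
        "sig_locs_visited": float(visited),
        "radius_of_gyration_m": rog,
    }


def clusters_to_frame(clusters: list[SigLocation]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "label": c.label,
            "lat": c.center[0],
            "lon": c.center[1],
            "radius_m": c.radius_m,
            "total_dwell_min": c.total_dwell_min,
            "night_dwell_min": c.night_dwell_min,
            "is_home": c.is_home,
            "low_confidence": c.low_confidence,
        }
        for c in clusters
    ])
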