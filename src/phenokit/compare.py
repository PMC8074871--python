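"""Pre/post regime comparison: windowed per-participant feature means with
paired t and Wilcoxon signed-rank tests.

The design mirrors a natural-experiment analysis of an abrupt behavioral
regime change (a stay-at-home order): for every feature, each participant
contributes one mean over a window before the event and one after, and the
cohort of paired means is tested with a paired t test and a Wilcoxon signed
rank test.  Default windows are day offsets [-45, -3] and [+3, +45]
inclusive (43 calendar days each), leaving a 5-day guard band around the
event.

The Wilcoxon p value is exact (full sign-flip enumeration via a rank
polynomial) up to n = 12 nonzero differences, and a tie-corrected,
continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BEFORE = (-45, -3)
DEFAULT_AFTER = (3, 45)
EXACT_WILCOXON_MAX_N = 12

#: the default feature set of the pre/post analysis
DEFAULT_COMPARE_FEATURES = [
    "accel_L_std",
    "accel_ddt_max",
    "ambient_hourly_max_log1p_lux",
    "n_incoming_calls",
    "hometime_min",
    "sig_locs_visited",
    "hourly_n_screen_on",
    "n_unique_apps",
    "n_taps_in_entertainment",
    "daily_n_steps",
    "daily_n_mins_walk",
    "hr_mean",
    "hr_min",
    "sleep_total_hrs",
    "sleep_mean_efficiency",
]


def window_means(
    daily: pd.DataFrame,
    event_date: dt.date,
    feature: str,
    before: tuple[int, int] = DEFAULT_BEFORE,
    after: tuple[int, int] = DEFAULT_AFTER,
    min_days: int = 7,
) -> pd.DataFrame:
    """Per-participant (before_mean, after_mean) for one feature.

    A participant qualifies iff both windows contain at least ``min_days``
    non-missing daily values.  Window offsets are inclusive of both
    endpoints.
    """
    days_rel = (pd.to_datetime(daily["date"]) - pd.Timestamp(event_date)).dt.days
    x = daily[feature]
    in_before = days_rel.between(before[0], before[1])
    in_after = days_rel.between(after[0], after[1])
    rows = []
    for pid, idx in daily.groupby("participant_id", sort=True).groups.items():
        vb = x.loc[idx][in_before.loc[idx]].dropna()
        va = x.loc[idx][in_after.loc[idx]].dropna()
        if len(vb) >= min_days and len(va) >= min_days:
            rows.append({"participant_id": pid,
                         "before_mean": float(vb.mean()),
                         "after_mean": float(va.mean())})
    return pd.DataFrame(rows, columns=["participant_id", "before_mean", "after_mean"])


def paired_t(before, after) -> tuple[float, float]:
    """Two-sided paired t test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.

    Returns (t, p); p is NaN (flagged undefined, never 0) when the
    differences have zero variance or n < 2.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError("before/after must be paired")
    d = a - b
    n = d.size
    if n < 2:
        return math.nan, math.nan
    sd = d.std(ddof=1)
    if sd == 0:
        return math.nan, math.nan
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Average ranks of |d| after dropping zero differences."""
    return stats.rankdata(np.abs(d))


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p via the distribution of W+ over all 2^n sign flips.

    Uses a polynomial (dynamic-programming) convolution over doubled ranks so
    tie-averaged half-integer ranks stay integral.  Two-sided p is
    2 * min(P(W+ <= w), P(W+ >= w)) capped at 1.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(before, after) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples; returns (W+, two-sided p).

    Zero differences are dropped; ties in |d| get average ranks.  Exact
    enumeration for up to 12 effective pairs, otherwise a normal
    approximation with tie and continuity corrections.  All differences zero
    => p is NaN (flagged undefined).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError("before/after must be paired")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return math.nan, math.nan
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        return w_plus, _exact_two_sided_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48.0).sum())
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, math.nan
    diff = w_plus - mean
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


@dataclass
class ComparisonRow:
    feature: str
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    p_paired_t: float
    p_wilcoxon: float
    n_pairs: int


def compare_table(
    daily: pd.DataFrame,
    event_date: dt.date,
    features: list[str] | None = None,
    before: tuple[int, int] = DEFAULT_BEFORE,
    after: tuple[int, int] = DEFAULT_AFTER,
    min_days: int = 7,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """One row per feature: across-participant mean (SD) of the windowed
    per-participant means, both p values, and the pair count.

    Unadjusted p values by default; ``bh_adjust`` adds Benjamini-Hochberg
    adjusted columns without replacing the raw ones.
    """
    features = features or [f for f in DEFAULT_COMPARE_FEATURES if f in daily.columns]
    rows = []
    for feat in features:
        wm = window_means(daily, event_date, feat, before, after, min_days)
        if not len(wm):
            rows.append(ComparisonRow(feat, *(math.nan,) * 6, 0))
            continue
        b = wm["before_mean"].to_numpy()
        a = wm["after_mean"].to_numpy()
        _, p_t = paired_t(b, a)
        _, p_w = wilcoxon_signed_rank(b, a)
        rows.append(ComparisonRow(
            feature=feat,
            mean_before=float(b.mean()),
            sd_before=float(b.std(ddof=1)) if b.size > 1 else math.nan,
            mean_after=float(a.mean()),
            sd_after=float(a.std(ddof=1)) if a.size > 1 else math.nan,
            p_paired_t=p_t,
            p_wilcoxon=p_w,
            n_pairs=int(len(wm)),
        ))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if bh_adjust:
        for col in ("p_paired_t", "p_wilcoxon"):
            out[col + "_bh"] = _benjamini_hochberg(out[col].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps)
    adj = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def format_mean_sd(mean: float, sd: float, sig: int = 4) -> str:
    if math.isnan(mean):
        return "-"
    return f"{mean:.4g} ({sd:.3g})"
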