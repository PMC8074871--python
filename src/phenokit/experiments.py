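"""Self-contained validation experiments the package uses to demonstrate its
own correctness and calibration on synthetic data.

Each experiment regenerates its inputs from a seed, runs the corresponding
pipeline stage, and returns plain numbers: the completion-rate aggregate of
the reference deployment table, oracle agreement for the paired tests,
anomaly-score calibration and changepoint detection, the synthetic
stay-at-home (regime-shift) experiment, and moment recovery against the
generator's planted truth.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import compare as cmp_mod
from .anomaly import anomaly_score, fit_forecaster, rolling_scores
from .completeness import overall_rate, reference_completion_table
from .compare import paired_t, wilcoxon_signed_rank
from .features import build_daily_table
from .simulate import (
    CohortConfig,
    default_cohort_config,
    generate_cohort,
    make_profiles,
    presence_truth,
)


def table1_overall() -> dict:
    """Unweighted mean of the reference per-feature completion rates."""
    ref = reference_completion_table()
    return {
        "overall_pct": overall_rate(ref["completion_rate_pct"]),
        "n_features": int(len(ref)),
    }


# ---------------------------------------------------------------------------
# Paired-test oracle agreement


def _enumeration_wilcoxon_p(d: np.ndarray) -> float:
    """Two-sided exact p by literal enumeration of all 2^n sign flips."""
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    ws = bits @ ranks
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_test_oracle_agreement(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Compare the package's exact Wilcoxon p against sign-flip enumeration
    and the paired-t p against an independent t implementation on random
    paired vectors (n <= 12, integer-valued so ties occur)."""
    rng = np.random.default_rng(seed)
    max_w = 0.0
    max_t = 0.0
    n_done = 0
    while n_done < n_vectors:
        n = int(rng.integers(3, 13))
        b = rng.integers(0, 5, n).astype(float)
        a = b + rng.integers(-3, 4, n)
        d = a - b
        if np.all(d == 0):
            continue
        _, p_w = wilcoxon_signed_rank(b, a)
        max_w = max(max_w, abs(p_w - _enumeration_wilcoxon_p(d)))
        if np.std(d, ddof=1) > 0 and n >= 2:
            _, p_t = paired_t(b, a)
            ref = stats.ttest_rel(a, b)
            max_t = max(max_t, abs(p_t - ref.pvalue))
        n_done += 1
    return {
        "n_vectors": n_vectors,
        "wilcoxon_max_abs_p_diff": max_w,
        "paired_t_max_abs_p_diff": max_t,
    }


# ---------------------------------------------------------------------------
# Anomaly calibration and detection


def anomaly_calibration(n_series: int = 200, n_days: int = 365,
                        seed: int = 0, model_kind: str = "seasonal_naive",
                        min_history: int = 21) -> dict:
    """Rolling scores on stationary i.i.d. Gaussian series: fraction of
    high-alert days and a pooled uniformity KS test."""
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_series):
        x = rng.normal(0.0, 1.0, n_days)
        r = rolling_scores(x, model_kind, min_history)
        pooled.append(r["score"].dropna().to_numpy())
    s = np.concatenate(pooled)
    ks = stats.kstest(s, "uniform")
    return {
        "n_scores": int(s.size),
        "frac_ge_095_pct": float(100.0 * np.mean(s >= 0.95)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def changepoint_detection(n_reps: int = 100, shift_sd: float = 3.0,
                          change_day: int = 200, seed: int = 0) -> dict:
    """Median score on the day of a planted level shift, per model."""
    out = {}
    for kind in ("seasonal_naive", "ar_weekly"):
        rng = np.random.default_rng(seed)
        scores = []
        for _ in range(n_reps):
            x = rng.normal(0.0, 1.0, change_day + 1)
            x[change_day] += shift_sd
            fr = fit_forecaster(x[:change_day], kind)
            scores.append(anomaly_score(fr.residuals, x[change_day] - fr.prediction))
        out[kind] = float(np.median(scores))
    return out


# ---------------------------------------------------------------------------
# Synthetic regime-shift (stay-at-home order analogue) experiment


#: daily-feature column per planted regime family, with the planted direction
REGIME_FEATURES = {
    "daily_n_steps": -1,
    "hometime_min": +1,
    "n_incoming_calls": -1,
    "hourly_n_screen_on": -1,
    "n_unique_apps": -1,
    "n_taps_in_entertainment": +1,
    "ambient_hourly_max_log1p_lux": -1,
    "accel_L_std": -1,
    "sleep_mean_efficiency": -1,
}


def regime_experiment(n_seeds: int = 20, n_participants: int = 22,
                      n_days: int = 90, seed: int = 0) -> dict:
    """Run the full generate -> features -> compare chain over seeded cohorts
    with the default planted regime shift and measure sign recovery and
    paired-t significance for the configured features.

    Effects realized at |Cohen's d| >= 0.5 on the paired differences are the
    ones held to the p < 0.05 bar.
    """
    rng = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(n_seeds)]
    sign_ok = []
    strong_sig = []
    for s in child_seeds:
        cfg = default_cohort_config(n_participants, n_days, seed=s)
        cohort = generate_cohort(cfg, seed=s)
        daily = build_daily_table(cohort)
        for feat, direction in REGIME_FEATURES.items():
            wm = cmp_mod.window_means(daily, cfg.event_date, feat)
            d = wm["after_mean"].to_numpy() - wm["before_mean"].to_numpy()
            sign_ok.append(np.sign(d.mean()) == direction)
            _, p_t = paired_t(wm["before_mean"], wm["after_mean"])
            cohen_d = abs(d.mean()) / d.std(ddof=1)
            if cohen_d >= 0.5:
                strong_sig.append(p_t < 0.05)
    return {
        "n_seeds": n_seeds,
        "n_feature_checks": len(sign_ok),
        "sign_recovery_pct": float(100.0 * np.mean(sign_ok)),
        "n_strong_effects": len(strong_sig),
        "strong_effect_significant_pct": float(100.0 * np.mean(strong_sig)),
    }


# ---------------------------------------------------------------------------
# Moment recovery


def moment_recovery(n_days: int = 150, seed: int = 0) -> dict:
    """Max |z| of empirical daily means vs the generator's planted truth for
    steps, sleep hours and hometime, plus completion-rate recovery (in
    Monte-Carlo standard errors)."""
    cfg = CohortConfig(profiles=make_profiles(2, seed), n_days=n_days, effect=None)
    cohort = generate_cohort(cfg, seed=seed)
    daily = build_daily_table(cohort)
    man = cohort.manifest
    zs = {}
    for metric in ("daily_n_steps", "sleep_total_hrs", "hometime_min"):
        worst = 0.0
        for pid in cohort.participants:
            v = daily[daily.participant_id == pid][metric].dropna()
            exp = man[(man.participant_id == pid)
                      & (man.metric == metric)].pre_expected.iloc[0]
            se = v.std() / math.sqrt(len(v))
            worst = max(worst, abs(v.mean() - exp) / se)
        zs[metric] = worst
    truth = presence_truth(cfg).set_index("stream")
    worst_c = 0.0
    for stream, p in truth["expected_presence"].items():
        sub = cohort.presence[cohort.presence.stream == stream]
        se = math.sqrt(p * (1 - p) / len(sub))
        worst_c = max(worst_c, abs(sub.file_present.mean() - p) / se)
    return {
        "n_days": n_days,
        "steps_recovery_z": zs["daily_n_steps"],
        "sleep_recovery_z": zs["sleep_total_hrs"],
        "hometime_recovery_z": zs["hometime_min"],
        "completion_recovery_z": worst_c,
    }
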