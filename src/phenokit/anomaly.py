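"""Daily-retrained one-step forecasting and empirical-residual anomaly scores.

The scoring contract: train a forecaster on all past data every day, predict
the next day, and transform the realized absolute prediction error into a
probability-like score by locating it in the empirical distribution of the
model's own training residuals (ties get half weight).  Scores live in
[0, 1]; higher values constitute alerts.  A day that cannot be scored
(insufficient history, missing observation, unavailable lagged values)
carries the NaN sentinel — never 0 or 1.

Forecasters capture the weekly periodicity of behavioral series:

* ``seasonal_naive`` — prediction is the value 7 days prior.
* ``ar_weekly`` — least squares of x_t on (x_{t-1}, x_{t-7}, day-of-week
  indicators); an autoregressive stand-in of the ARIMA family.
* ``gp_periodic`` — Gaussian-process posterior mean with a squared
  exponential plus 7-day periodic kernel.

The interface is pluggable so the scoring routine can be swapped without
touching the dashboard layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODEL_KINDS = ("seasonal_naive", "ar_weekly", "gp_periodic")


@dataclass
class ForecastResult:
    prediction: float            # NaN when the model cannot predict
    residuals: np.ndarray        # training one-step errors
    model_kind: str


def fit_forecaster(values: np.ndarray, model_kind: str = "seasonal_naive",
                   dow0: int = 0) -> ForecastResult:
    """Fit on a daily history (NaN = missing) and predict the next day.

    ``values`` are the observations for consecutive calendar days; ``dow0``
    is the weekday (0=Monday) of values[0].  Residuals are in-sample one-step
    errors computed only on days where the model's inputs and the target are
    all observed.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if model_kind == "seasonal_naive":
        if n < 7:
            return ForecastResult(np.nan, np.array([]), model_kind)
        r = x[7:] - x[:-7]
        pred = x[n - 7]
        return ForecastResult(float(pred) if np.isfinite(pred) else np.nan,
                              r[np.isfinite(r)], model_kind)

    if model_kind == "ar_weekly":
        if n < 8:
            return ForecastResult(np.nan, np.array([]), model_kind)
        t = np.arange(7, n)
        y = x[t]
        X = _ar_design(x, t, dow0)
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        if ok.sum() < X.shape[1] + 2:
            return ForecastResult(np.nan, np.array([]), model_kind)
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        resid = y[ok] - X[ok] @ beta
        # in-sample OLS residuals are variance-shrunk; rescale to the unbiased
        # one-step error scale so empirical-tail scores stay calibrated
        m, p = int(ok.sum()), X.shape[1]
        if m > p:
            resid = resid * math.sqrt(m / (m - p))
        Xn = _ar_design(x, np.array([n]), dow0)
        pred = float((Xn @ beta)[0]) if np.all(np.isfinite(Xn)) else np.nan
        return ForecastResult(pred, resid, model_kind)

    if model_kind == "gp_periodic":
        return _fit_gp(x, dow0)

    raise ValueError(f"unknown model kind {model_kind!r}")


def _ar_design(x: np.ndarray, t: np.ndarray, dow0: int, next_day: bool = False) -> np.ndarray:
    n = x.size
    lag1 = x[t - 1]
    lag7 = x[t - 7]
    dow = (t + dow0) % 7
    D = np.zeros((t.size, 6))
    for k in range(1, 7):
        D[:, k - 1] = dow == k
    return np.column_stack([np.ones(t.size), lag1, lag7, D])


def _fit_gp(x: np.ndarray, dow0: int) -> ForecastResult:
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ExpSineSquared, WhiteKernel

    n = x.size
    obs = np.flatnonzero(np.isfinite(x))
    if obs.size < 14:
        return ForecastResult(np.nan, np.array([]), "gp_periodic")
    obs = obs[-120:]  # cap the training window for tractability
    y = x[obs]
    mu, sd = y.mean(), max(y.std(), 1e-9)
    kernel = (RBF(length_scale=14.0) + ExpSineSquared(length_scale=1.0, periodicity=7.0)
              + WhiteKernel(noise_level=0.5))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False, optimizer=None)
    gp.fit(obs.reshape(-1, 1), (y - mu) / sd)
    fitted = gp.predict(obs.reshape(-1, 1)) * sd + mu
    resid = y - fitted
    pred = float(gp.predict(np.array([[n]]))[0] * sd + mu)
    return ForecastResult(pred, resid, "gp_periodic")


def anomaly_score(residuals: np.ndarray, new_error: float) -> float:
    """Empirical tail probability of |new error| among |training residuals|.

    score = (#{|r| < |e|} + 0.5 #{|r| = |e|}) / T; a zero realized error is
    never anomalous (score 0).  Empty residual set => NaN sentinel.
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    r = r[np.isfinite(r)]
    if r.size == 0 or not np.isfinite(new_error):
        return np.nan
    e = abs(float(new_error))
    if e == 0.0:
        return 0.0
    return float((np.count_nonzero(r < e) + 0.5 * np.count_nonzero(r == e)) / r.size)


def rolling_scores(series: pd.Series | np.ndarray, model_kind: str = "seasonal_naive",
                   min_history: int = 21, dow0: int = 0) -> pd.DataFrame:
    """Expanding-window daily scores: for each day t, fit on days < t only.

    Never peeks at day t or later; a missing observation yields the NaN
    sentinel for that day while leaving the model window untouched.
    Returns columns: day, prediction, error, score.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    day = np.arange(n)
    pred = np.full(n, np.nan)
    err = np.full(n, np.nan)
    score = np.full(n, np.nan)
    for t in range(n):
        hist = x[:t]
        if np.count_nonzero(np.isfinite(hist)) < min_history:
            continue
        fr = fit_forecaster(hist, model_kind, dow0)
        if not np.isfinite(fr.prediction) or not np.isfinite(x[t]):
            continue
        pred[t] = fr.prediction
        err[t] = x[t] - fr.prediction
        score[t] = anomaly_score(fr.residuals, err[t])
    return pd.DataFrame({"day": day, "prediction": pred, "error": err, "score": score})


def multivariate_score(errors: dict[str, float], residual_sds: dict[str, float]) -> float:
    """Chi-square combination of per-feature standardized errors.

    Q = sum_k (e_k / sigma_k)^2 referred to a chi-square CDF with K degrees of
    freedom (diagonal standardization; cross-feature covariance is not
    modeled).  Fewer than 2 usable features => NaN sentinel.
    """
    q = 0.0
    k = 0
    for name, e in errors.items():
        sd = residual_sds.get(name, np.nan)
        if np.isfinite(e) and np.isfinite(sd) and sd > 0:
            q += (e / sd) ** 2
            k += 1
    if k < 2:
        return np.nan
    return float(stats.chi2.cdf(q, df=k))


# ---------------------------------------------------------------------------
# Scoring a daily feature table


def score_table(
    daily: pd.DataFrame,
    feature_cols: list[str],
    model_kind: str = "ar_weekly",
    min_history: int = 21,
) -> pd.DataFrame:
    """Latest-day anomaly scores per participant and feature, plus the
    multivariate score and the last date scores were successfully updated."""
    rows = []
    for pid, sub in daily.groupby("participant_id", sort=True):
        sub = sub.sort_values("date")
        dates = list(sub["date"])
        dow0 = pd.Timestamp(dates[0]).weekday()
        row: dict = {"participant_id": pid}
        errors: dict[str, float] = {}
        sds: dict[str, float] = {}
        last_update = None
        for col in feature_cols:
            x = sub[col].to_numpy(dtype=float)
            hist, target = x[:-1], x[-1]
            sc = np.nan
            if np.count_nonzero(np.isfinite(hist)) >= min_history and np.isfinite(target):
                fr = fit_forecaster(hist, model_kind, dow0)
                if np.isfinite(fr.prediction) and fr.residuals.size:
                    e = target - fr.prediction
                    sc = anomaly_score(fr.residuals, e)
                    errors[col] = e
                    sds[col] = float(np.std(fr.residuals)) if fr.residuals.size else np.nan
                    last_update = dates[-1]
            row[col] = sc
        row["multivariate"] = multivariate_score(errors, sds)
        row["last_update_date"] = last_update
        rows.append(row)
    return pd.DataFrame(rows)


def rolling_score_table(
    daily: pd.DataFrame,
    feature_cols: list[str],
    model_kind: str = "ar_weekly",
    min_history: int = 21,
) -> pd.DataFrame:
    """Per-day rolling scores for every participant and feature (long form)."""
    frames = []
    for pid, sub in daily.groupby("participant_id", sort=True):
        sub = sub.sort_values("date")
        dow0 = pd.Timestamp(sub["date"].iloc[0]).weekday()
        for col in feature_cols:
            r = rolling_scores(sub[col].to_numpy(dtype=float), model_kind,
                               min_history, dow0)
            r.insert(0, "participant_id", pid)
            r.insert(1, "feature", col)
            r["date"] = list(sub["date"])
            frames.append(r)
    return pd.concat(frames, ignore_index=True)
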