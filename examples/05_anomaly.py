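"""Daily-retrained forecasting and empirical-residual anomaly scores.

A behavioral series with weekly structure is scored day by day: the model is
refit on all past data, predicts the next day, and the realized error is
located in the empirical distribution of the training residuals. A planted
level shift shows up as a run of scores near 1.
"""

import numpy as np

from phenokit.anomaly import rolling_scores

rng = np.random.default_rng(0)
days = np.arange(120)
x = 6000 + 800 * (days % 7 >= 5) + rng.normal(0, 300, days.size)  # weekend bump
x[100:] -= 2500  # abrupt behavioral change at day 100

r = rolling_scores(x, model_kind="ar_weekly", min_history=21)
print("day  score   (NaN until enough history)")
for d in [20, 21, 50, 99, 100, 101, 105]:
    print(f"{d:3d}  {r['score'][d]:.3f}" if np.isfinite(r['score'][d])
          else f"{d:3d}  no score")
print(f"\nmean score days 22-99:   {np.nanmean(r['score'][22:100]):.3f} "
      "(unremarkable days hover near the middle of [0,1])")
print(f"score on shift day 100:  {r['score'][100]:.3f} (alert: >= 0.95)")
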