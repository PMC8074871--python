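"""Significant locations, home inference and daily mobility metrics.

Clusters a participant's GPS trace (greedy chronological density pass),
infers home as the cluster with the most nocturnal dwell, and computes the
daily hometime / time-away / radius-of-gyration bookkeeping. Coordinates
shown are already privacy-displaced; the metrics are translation invariant.
"""

import phenokit as pk
from phenokit.mobility import cluster_significant_locations, daily_mobility, infer_home

cfg = pk.default_cohort_config(n_participants=1, n_days=30, seed=5,
                               with_effect=False)
cohort = pk.generate_cohort(cfg, seed=5)
pdata = next(iter(cohort.participants.values()))

gps_days = [s["gps"] for s in pdata.days.values() if "gps" in s]
clusters = cluster_significant_locations(gps_days, eps_m=100, min_dwell_min=30)
home = infer_home(clusters)
print(f"{len(clusters)} significant locations; home = cluster {home.label} "
      f"with {home.night_dwell_min:.0f} nocturnal dwell minutes")

for day in gps_days[:5]:
    m = daily_mobility(day, home, clusters)
    print(f"{day.date}: hometime {m['hometime_min']:6.0f} min, "
          f"away {m['time_away_from_home_min']:4.0f} min, "
          f"visited {m['sig_locs_visited']:.0f} places, "
          f"max distance from home {m['radius_of_gyration_m']:6.0f} m")
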