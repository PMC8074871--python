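"""Raw streams -> daily behavioral feature table.

Every row is one participant-day; every feature is either a value or an
explicit missing marker. missing_not_worn on wearable features marks days
the heart-rate trace says the device was off — those days are never reported
as zero sleep or zero steps.
"""

import phenokit as pk

cfg = pk.default_cohort_config(n_participants=2, n_days=20, seed=3,
                               with_effect=False)
cohort = pk.generate_cohort(cfg, seed=3)
daily = pk.build_daily_table(cohort)

cols = ["participant_id", "date", "daily_n_steps", "sleep_total_hrs",
        "sleep_mean_efficiency", "hometime_min", "n_msgs_exchanged"]
print(daily[cols].head(10).to_string(index=False))

nw = daily[daily["sleep_total_hrs__status"] == "missing_not_worn"]
print(f"\n{len(nw)} of {len(daily)} days ruled not-worn overnight "
      f"(sleep/steps/heart features withheld rather than zeroed)")
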