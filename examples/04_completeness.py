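"""Completion rates and the reference deployment aggregate.

A stream-day counts as collected iff its daily file exists - an empty call
log is a day with no calls, not a collection failure. The per-feature rates
pool participant-days; the Overall row is their unweighted mean. The same
aggregation applied to the shipped reference table (a 22-participant
smartphone + wearable deployment) reproduces its published overall figure.
"""

import phenokit as pk
from phenokit.completeness import (
    completion_report, overall_rate, reference_completion_table)

cfg = pk.default_cohort_config(n_participants=3, n_days=30, seed=9,
                               with_effect=False)
cohort = pk.generate_cohort(cfg, seed=9)
rep = completion_report(cohort.presence)
print("synthetic cohort (planted ~95% phone / 90% wearable presence):")
print(rep.to_string(index=False))

ref = reference_completion_table()
print(f"\nreference deployment: {len(ref)} features, "
      f"overall = {overall_rate(ref['completion_rate_pct'])}%")
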