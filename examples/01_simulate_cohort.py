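"""Generate a small synthetic cohort and inspect its planted truth.

Builds 3 participants x 30 days of all 13 sensor streams with the default
missingness, writes nothing to disk, and prints the closed-form expectations
the generator planted for the first participant. These expectations are what
the feature pipeline is later tested against.
"""

import phenokit as pk

cfg = pk.default_cohort_config(n_participants=3, n_days=30, seed=7,
                               with_effect=False)
cohort = pk.generate_cohort(cfg, seed=7)

pid = next(iter(cohort.participants))
pdata = cohort.participants[pid]
one_day = next(iter(pdata.days.values()))
print(f"participant {pid}: {len(pdata.days)} days, "
      f"{len(one_day)} streams present on day 1")

man = cohort.manifest
man = man[(man.participant_id == pid) & man.pre_expected.notna()]
print("\nplanted daily expectations (no regime effect, pre == post):")
print(man[["metric", "pre_expected"]].to_string(index=False))

absent = cohort.missing_days
print(f"\nplanted missing stream-days: {len(absent)} "
      f"(e.g. non-wear removes heart/steps/sleep together)")
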