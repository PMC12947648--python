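"""Generate the synthetic SPAN cohort that stands in for the study sample.

Writes results/analysis/cohort.csv (+ provenance JSON) and prints the
exposure marginals so they can be eyeballed against the published tertile
ranges (sleep 4.8-7.2 / 7.2-8.0 / 8.0-9.4 h/day; MVPA 5-23 / 23-42 / 42-103
min/day; DQS 32.5-50 / 50-57.5 / 57.5-72.5)."""

import numpy as np

from common import N_PARTICIPANTS, SEED, out_path
from spanlife.synthgen import SynthConfig, generate_cohort

config = SynthConfig(n_participants=N_PARTICIPANTS, seed=SEED,
                     baseline_mortality_rate=0.02)
cohort = generate_cohort(config, out_path("cohort.csv"))

print(f"cohort: n={len(cohort)}, deaths={int(cohort.death.sum())}, "
      f"median follow-up={cohort.followup_y.median():.1f} y")
for col, unit in (("sleep_h", "h/day"), ("mvpa_min", "min/day"), ("dqs", "points")):
    q = np.percentile(cohort[col], [2.5, 100 / 3, 50, 200 / 3, 97.5])
    print(f"  {col:9s} 2.5%={q[0]:6.1f}  t1={q[1]:6.1f}  median={q[2]:6.1f}  "
          f"t2={q[3]:6.1f}  97.5%={q[4]:6.1f}  [{unit}]")
events = {c: int(cohort[f"e_{c}"].sum())
          for c in ("cvd", "cancer", "t2d", "copd", "dementia")}
print(f"  first-incidence events: {events}")
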