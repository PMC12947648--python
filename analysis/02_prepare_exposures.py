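"""Clean and categorise the exposures: winsorise at the 2.5/97.5 percentiles,
drop first-year deaths, assign tertiles on the winsorised values, and build
the 27-category joint sleep x MVPA x diet variable plus the combined
disease-free exit outcome.

Writes prepared_cohort.csv, tertile_schemes.json and exclusion_log.json."""

import dataclasses
import json

from common import load, out_path
from spanlife.pipeline import disease_free_outcome
from spanlife.prep import (ExclusionRules, apply_exclusions, assign_tertiles,
                           make_joint_categories, winsorise)

cohort = load("cohort.csv")
cohort, excl_log = apply_exclusions(cohort, ExclusionRules(drop_death_within_years=1.0))
print(f"exclusions: {excl_log['rules']} -> n={excl_log['n_out']}")

schemes = {}
for col, name in (("sleep_h", "sleep"), ("mvpa_min", "mvpa"), ("dqs", "dqs")):
    cohort[f"{col}_w"] = winsorise(cohort[col])
    schemes[name], cohort[f"{name}_t"] = assign_tertiles(cohort[f"{col}_w"], name)
    s = schemes[name]
    print(f"  {name:5s} tertiles: {s.observed_min:.1f}-{s.cut_low_med:.1f} (low) "
          f"{s.cut_low_med:.1f}-{s.cut_med_high:.1f} (medium) "
          f"{s.cut_med_high:.1f}-{s.observed_max:.1f} (high)")

cohort["joint_category"] = make_joint_categories(cohort["sleep_t"],
                                                 cohort["mvpa_t"], cohort["dqs_t"])
cohort = disease_free_outcome(cohort)
print(f"deaths={int(cohort.death.sum())}, disease-free exits={int(cohort.e_dfree.sum())}")

cohort.to_csv(out_path("prepared_cohort.csv"), index=False)
out_path("tertile_schemes.json").write_text(json.dumps(
    {k: dataclasses.asdict(v) for k, v in schemes.items()}, indent=2))
out_path("exclusion_log.json").write_text(json.dumps(excl_log, indent=2))
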