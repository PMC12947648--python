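"""Synergy indices (RERI/AP/S with bootstrap CIs), the composite SPAN score
dose-response, and the minimum combined behaviour doses per year of lifespan
and healthspan gained.

Writes synergy.csv, score_gain_curve_{lifespan,healthspan}.csv,
min_dose_{lifespan,healthspan}.csv and heatmap_sleep_mvpa.csv."""

import json

import numpy as np
import pandas as pd

from common import START_AGE, SEED, load, out_path
from spanlife.healthspan import combined_exit_rates, disease_free_life_expectancy
from spanlife.lifetable import LEGainEstimate
from spanlife.pipeline import DEFAULT_COVARIATES, build_score_mappings
from spanlife.prep import TertileScheme
from spanlife.rates import synthetic_disease_rates, synthetic_mortality_rates
from spanlife.spanscore import (composite_score, derive_weights, heatmap_grid,
                                lifespan_gain_curve, minimum_dose_table)
from spanlife.survmodel import fit_cox_rcs
from spanlife.synergy import binarize_exposures, bootstrap_synergy

cohort = load("prepared_cohort.csv")
mortality = synthetic_mortality_rates()
disease = synthetic_disease_rates()

# ---- synergy (unadjusted occurrence/exposure bootstrap for speed) ----------
cohort["joint_state"] = binarize_exposures(cohort["sleep_t"], cohort["mvpa_t"],
                                           cohort["dqs_t"])
syn_rows = []
for outcome, (dur, ev) in {"mortality": ("followup_y", "death"),
                           "diseasefree": ("t_dfree", "e_dfree")}.items():
    ind = bootstrap_synergy(cohort, dur, ev, B=500, seed=SEED + 2,
                            estimator="rate")
    syn_rows.append(ind.as_row(outcome))
    lo, hi = ind.ci["reri"]
    print(f"{outcome:12s} RERI={ind.reri:+.3f} (95% CI {lo:+.3f}, {hi:+.3f})  "
          f"AP={ind.ap:+.3f}  S={'NA' if ind.s is None else f'{ind.s:.3f}'}")
pd.DataFrame(syn_rows).to_csv(out_path("synergy.csv"), index=False)

# ---- composite score and dose-response -------------------------------------
schemes = {k: TertileScheme(**v)
           for k, v in json.loads(out_path("tertile_schemes.json").read_text()).items()}
mappings = build_score_mappings(schemes)
cohort["span_score"] = composite_score(cohort["sleep_h_w"].to_numpy(),
                                       cohort["mvpa_min_w"].to_numpy(),
                                       cohort["dqs_w"].to_numpy(), mappings)
weights = derive_weights(load("hr_joint_mortality.csv"))
reference = {b: float(np.percentile(cohort[c], 5))
             for b, c in (("sleep", "sleep_h_w"), ("mvpa", "mvpa_min_w"),
                          ("dqs", "dqs_w"))}
print(f"behaviour weights: {weights.as_dict()}")
print(f"5th-percentile reference: sleep {reference['sleep']:.1f} h, "
      f"MVPA {reference['mvpa']:.1f} min, DQS {reference['dqs']:.1f}")

sp_mort = fit_cox_rcs(cohort, "followup_y", "death", "span_score",
                      DEFAULT_COVARIATES)
sp_dfree = fit_cox_rcs(cohort, "t_dfree", "e_dfree", "span_score",
                       DEFAULT_COVARIATES)
grid = np.arange(sp_mort.reference_value, cohort["span_score"].max(), 0.5)


def dfle_gain(hr_row):
    def one(h):
        ex = combined_exit_rates(mortality, disease, h, h)
        return disease_free_life_expectancy(ex, disease, START_AGE)[1]
    base = one(1.0)
    return LEGainEstimate("", one(hr_row["hr"]) - base,
                          one(hr_row["ci_high"]) - base,
                          one(hr_row["ci_low"]) - base)


curve_life = lifespan_gain_curve(sp_mort, mortality, grid, START_AGE)
curve_health = lifespan_gain_curve(sp_dfree, mortality, grid, START_AGE,
                                   gain_fn=dfle_gain)
curve_life.to_csv(out_path("score_gain_curve_lifespan.csv"), index=False)
curve_health.to_csv(out_path("score_gain_curve_healthspan.csv"), index=False)

singles_life, singles_health = {}, {}
for b, col in (("sleep", "sleep_h_w"), ("mvpa", "mvpa_min_w"), ("dqs", "dqs_w")):
    bgrid = np.linspace(reference[b], mappings[b].floor_high, 80)
    singles_life[b] = lifespan_gain_curve(
        fit_cox_rcs(cohort, "followup_y", "death", col, DEFAULT_COVARIATES),
        mortality, bgrid, START_AGE)
    singles_health[b] = lifespan_gain_curve(
        fit_cox_rcs(cohort, "t_dfree", "e_dfree", col, DEFAULT_COVARIATES),
        mortality, bgrid, START_AGE, gain_fn=dfle_gain)

for name, curve, singles, targets in (
        ("min_dose_lifespan.csv", curve_life, singles_life, range(1, 11)),
        ("min_dose_healthspan.csv", curve_health, singles_health, range(1, 9))):
    table = minimum_dose_table(curve, weights, mappings, reference,
                               sp_mort.reference_value, list(targets), singles)
    table.to_csv(out_path(name), index=False)
    reachable = table[table["reachable"] == True]  # noqa: E712
    if len(reachable):
        r = reachable.iloc[0]
        print(f"{name}: first entry at +{r.delta_score:.1f} score points -> "
              f"+{r.delta_sleep_min:.0f} min sleep, +{r.delta_mvpa_min:.1f} min "
              f"MVPA, +{r.delta_dqs:.1f} DQS (gain {r.years:.2f} y)")

medians = {b: float(cohort[c].median())
           for b, c in (("sleep", "sleep_h_w"), ("mvpa", "mvpa_min_w"),
                        ("dqs", "dqs_w"))}
heat = heatmap_grid(sp_mort, mortality, mappings, reference, START_AGE,
                    "sleep", "mvpa", medians, n_cells=12)
heat.to_csv(out_path("heatmap_sleep_mvpa.csv"), index=False)
print("wrote heatmap grid (sleep x MVPA at median DQS)")
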