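"""End-to-end orchestration: cohort -> prepared exposures -> hazard models ->
lifespan / healthspan tables -> synergy -> composite-score minimum doses.

Every numeric stage lives in its own module; this one wires them together,
derives per-stage random substreams from the single global seed (so toggling
one stage never shifts another's draws), logs row/event counts at stage
boundaries, and writes all outputs as CSV/JSON into a versioned run directory
with a manifest of SHA-256 checksums and the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .healthspan import (CONDITIONS, MonteCarloConfig, combined_exit_rates,
                         dfle_gain_mc, disease_free_life_expectancy)
from .lifetable import build_life_table, years_gained
from .prep import (ExclusionRules, apply_exclusions, assign_tertiles,
                   make_joint_categories, tukey_fence_bounds, winsorise)
from .rates import synthetic_disease_rates, synthetic_mortality_rates
from .spanscore import (ScoreMapping, composite_score, derive_weights,
                        heatmap_grid, lifespan_gain_curve, minimum_dose_table)
from .survmodel import fit_cox_joint, fit_cox_rcs, hazard_ratios, ph_diagnostics
from .synergy import binarize_exposures, bootstrap_synergy
from .synthgen import SynthConfig, generate_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "emit_outputs",
           "build_score_mappings", "disease_free_outcome"]

DEFAULT_COVARIATES = ["age", "sex", "smoking", "deprivation", "alcohol",
                      "screen_h", "lipa_min"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception, manifest: list):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    seed: int = 0
    input_mode: str = "synthetic"            # synthetic | cohort_csv
    cohort_csv: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    exclusions: ExclusionRules = field(default_factory=ExclusionRules)
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    winsor_mode: str = "percentile"          # percentile | tukey | none
    winsor_bounds: tuple = (2.5, 97.5)
    start_age: float = 64.0
    calibration: str = "none"
    mc_iterations: int = 2000
    bootstrap_B: int = 500
    synergy_estimator: str = "cox"
    sleep_nadir: float = 7.5
    mvpa_optimum: float = 50.0
    score_grid_step: float = 0.5
    lifespan_targets: list = field(default_factory=lambda: list(range(1, 11)))
    healthspan_targets: list = field(default_factory=lambda: list(range(1, 9)))
    heatmap_cells: int = 12
    run_diagnostics: bool = True

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "cohort_csv"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "cohort_csv" and not self.cohort_csv:
            raise ValueError("cohort_csv input mode needs a path")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict()
        d["winsor_bounds"] = list(self.winsor_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d:
            d["synth"] = SynthConfig.from_dict(d["synth"])
        if "exclusions" in d and isinstance(d["exclusions"], dict):
            d["exclusions"] = ExclusionRules(**d["exclusions"])
        if "winsor_bounds" in d:
            d["winsor_bounds"] = tuple(d["winsor_bounds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "seed" not in d:
            raise ValueError("pipeline config must set a seed")
        if "synth" in d:
            d["synth"].setdefault("seed", d["seed"])
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    manifest: list = field(default_factory=list)
    out_dir: str = ""

    def log_stage(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stage helpers

def disease_free_outcome(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add combined disease-free exit time/event columns (first of death or
    any condition's first incidence)."""
    df = cohort.copy()
    times = [np.where(df[f"e_{c}"] == 1, df[f"t_{c}"], np.inf) for c in CONDITIONS]
    times.append(np.where(df["death"] == 1, df["followup_y"], np.inf))
    first = np.minimum.reduce(times)
    df["e_dfree"] = (np.isfinite(first)).astype(int)
    df["t_dfree"] = np.minimum(first, df["followup_y"])
    return df


def build_score_mappings(schemes: dict, sleep_nadir: float = 7.5,
                         mvpa_optimum: float = 50.0) -> dict:
    """Score mappings anchored at the winsorised tertile-scheme extremes."""
    s, m, d = schemes["sleep"], schemes["mvpa"], schemes["dqs"]
    return {
        "sleep": ScoreMapping("sleep", "u_shaped", sleep_nadir,
                              s.observed_min, s.observed_max),
        "mvpa": ScoreMapping("mvpa", "saturating",
                             min(mvpa_optimum, m.observed_max),
                             m.observed_min, m.observed_max),
        "dqs": ScoreMapping("dqs", "monotone", d.observed_max,
                            d.observed_min, d.observed_max),
    }


def _versioned_dir(out_dir) -> Path:
    base = Path(out_dir)
    base.mkdir(parents=True, exist_ok=True)
    k = 1
    while (base / f"run_{k:03d}").exists():
        k += 1
    run = base / f"run_{k:03d}"
    run.mkdir()
    return run


def _write(obj, path: Path, manifest: list, config_hash: str) -> None:
    if isinstance(obj, pd.DataFrame):
        with open(path, "w") as fh:
            fh.write(f"# config_hash={config_hash}\n")
            obj.to_csv(fh, index=False)
    else:
        payload = {"config_hash": config_hash, **obj} if isinstance(obj, dict) else obj
        path.write_text(json.dumps(payload, indent=2, default=str))
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest.append({"file": path.name, "sha256": digest})


# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    """Execute all stages; returns the run report (also written to disk)."""
    run_dir = _versioned_dir(out_dir)
    chash = config.config_hash()
    report = RunReport(config_hash=chash, version=__version__,
                       seed=config.seed, out_dir=str(run_dir))
    manifest = report.manifest
    ss = np.random.SeedSequence(config.seed)
    # fixed substream layout: synth, synergy, mc, (spare)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]

    caught: list[warnings.WarningMessage] = []

    def stage(name):
        class _Ctx:
            def __enter__(self):  # noqa: D401
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc, manifest) from exc
                return False
        return _Ctx()

    # ---- synthgen / input --------------------------------------------------
    with stage("synthgen"):
        if config.input_mode == "synthetic":
            synth = dataclasses.replace(config.synth, seed=seeds[0])
            cohort = generate_cohort(synth, run_dir / "cohort.csv")
        else:
            cohort = pd.read_csv(config.cohort_csv)
        report.log_stage("synthgen", n=len(cohort), deaths=int(cohort["death"].sum()))

    # ---- prep --------------------------------------------------------------
    with stage("prep"):
        cohort, excl_log = apply_exclusions(cohort, config.exclusions)
        schemes = {}
        with warnings.catch_warnings(record=True) as caught_w:
            warnings.simplefilter("always")
            for col, name in (("sleep_h", "sleep"), ("mvpa_min", "mvpa"),
                              ("dqs", "dqs")):
                if config.winsor_mode == "percentile":
                    w = winsorise(cohort[col], *config.winsor_bounds)
                elif config.winsor_mode == "tukey":
                    lo, hi = tukey_fence_bounds(cohort[col])
                    w = cohort[col].clip(lo, hi)
                else:
                    w = cohort[col].copy()
                cohort[f"{col}_w"] = w
                scheme, labels = assign_tertiles(w, name)
                schemes[name] = scheme
                cohort[f"{name}_t"] = labels
        caught.extend(caught_w)
        cohort["joint_category"] = make_joint_categories(
            cohort["sleep_t"], cohort["mvpa_t"], cohort["dqs_t"])
        cohort = disease_free_outcome(cohort)
        _write(cohort, run_dir / "prepared_cohort.csv", manifest, chash)
        _write(excl_log, run_dir / "exclusion_log.json", manifest, chash)
        _write({"schemes": {k: dataclasses.asdict(v) for k, v in schemes.items()}},
               run_dir / "tertile_schemes.json", manifest, chash)
        report.log_stage("prep", n=len(cohort),
                         excluded=excl_log["removed_total"],
                         deaths=int(cohort["death"].sum()),
                         dfree_events=int(cohort["e_dfree"].sum()))

    # ---- survmodel -----------------------------------------------------------
    with stage("survmodel"):
        with warnings.catch_warnings(record=True) as caught_w:
            warnings.simplefilter("always")
            fit_mort = fit_cox_joint(cohort, "followup_y", "death",
                                     covariates=config.covariates)
            fit_dfree = fit_cox_joint(cohort, "t_dfree", "e_dfree",
                                      covariates=config.covariates)
        caught.extend(caught_w)
        hr_mort = hazard_ratios(fit_mort)
        hr_dfree = hazard_ratios(fit_dfree)
        _write(hr_mort, run_dir / "hr_joint_mortality.csv", manifest, chash)
        _write(hr_dfree, run_dir / "hr_joint_diseasefree.csv", manifest, chash)
        if config.run_diagnostics:
            diag = ph_diagnostics(fit_mort,
                                  continuous_covariates=[c for c in config.covariates
                                                         if c in ("age", "deprivation",
                                                                  "alcohol", "screen_h",
                                                                  "lipa_min")])
            _write(diag, run_dir / "ph_diagnostics_mortality.json", manifest, chash)
        report.log_stage("survmodel", mortality_events=fit_mort.n_events,
                         dfree_events=fit_dfree.n_events,
                         zero_event_categories=len(fit_mort.zero_event_categories))

    # ---- life tables ---------------------------------------------------------
    with stage("lifetable"):
        mort_rates = synthetic_mortality_rates()
        disease = synthetic_disease_rates()
        ref_table = build_life_table(mort_rates, config.start_age)
        _write(ref_table, run_dir / "life_table_reference.csv", manifest, chash)
        gain_rows = []
        for _, r in hr_mort.iterrows():
            if not np.isfinite(r["hr"]):
                continue
            est = years_gained(r, mort_rates, config.start_age,
                               config.calibration)
            gain_rows.append({"category_index": int(r["category_index"]),
                              "sleep_t": r["sleep_t"], "mvpa_t": r["mvpa_t"],
                              "diet_t": r["diet_t"], "hr": r["hr"],
                              "lifespan_years": est.years_gained,
                              "lifespan_lo": est.ci_low,
                              "lifespan_hi": est.ci_high})
        forest = pd.DataFrame(gain_rows)
        report.log_stage("lifetable", categories=len(forest))

    # ---- healthspan ----------------------------------------------------------
    with stage("healthspan"):
        mc = MonteCarloConfig(iterations=max(config.mc_iterations, 100),
                              seed=seeds[2])
        hr_d = hr_dfree.set_index("category_index")
        hs_rows = {}
        for _, r in hr_mort.iterrows():
            cat = int(r["category_index"])
            if not (np.isfinite(r["hr"]) and cat in hr_d.index
                    and np.isfinite(hr_d.loc[cat, "hr"])):
                continue
            est = dfle_gain_mc(r, mort_rates, disease, mc, config.start_age,
                               hr_incidence=hr_d.loc[cat])
            hs_rows[cat] = est
        forest["healthspan_years"] = forest["category_index"].map(
            lambda c: hs_rows[c].years_gained if c in hs_rows else np.nan)
        forest["healthspan_lo"] = forest["category_index"].map(
            lambda c: hs_rows[c].ci_low if c in hs_rows else np.nan)
        forest["healthspan_hi"] = forest["category_index"].map(
            lambda c: hs_rows[c].ci_high if c in hs_rows else np.nan)
        _write(forest, run_dir / "forest_gains.csv", manifest, chash)
        report.log_stage("healthspan", categories=len(hs_rows),
                         mc_iterations=mc.iterations)

    # ---- synergy -------------------------------------------------------------
    with stage("synergy"):
        cohort["joint_state"] = binarize_exposures(
            cohort["sleep_t"], cohort["mvpa_t"], cohort["dqs_t"])
        syn_rows = []
        for outcome, (dur, ev) in {"mortality": ("followup_y", "death"),
                                   "diseasefree": ("t_dfree", "e_dfree")}.items():
            covs = config.covariates if config.synergy_estimator == "cox" else None
            ind = bootstrap_synergy(cohort, dur, ev, B=config.bootstrap_B,
                                    seed=seeds[1], covariates=covs,
                                    estimator=config.synergy_estimator)
            syn_rows.append(ind.as_row(outcome))
        syn = pd.DataFrame(syn_rows)
        _write(syn, run_dir / "synergy.csv", manifest, chash)
        report.log_stage("synergy", outcomes=len(syn_rows), B=config.bootstrap_B)

    # ---- composite score / minimum dose ---------------------------------------
    with stage("spanscore"):
        mappings = build_score_mappings(schemes, config.sleep_nadir,
                                        config.mvpa_optimum)
        cohort["span_score"] = composite_score(
            cohort["sleep_h_w"].to_numpy(), cohort["mvpa_min_w"].to_numpy(),
            cohort["dqs_w"].to_numpy(), mappings)
        weights = derive_weights(hr_mort)
        reference = {"sleep": float(np.percentile(cohort["sleep_h_w"], 5)),
                     "mvpa": float(np.percentile(cohort["mvpa_min_w"], 5)),
                     "dqs": float(np.percentile(cohort["dqs_w"], 5))}
        _write({"weights": weights.as_dict(), "reference": reference},
               run_dir / "weights.json", manifest, chash)

        spline_mort = fit_cox_rcs(cohort, "followup_y", "death", "span_score",
                                  config.covariates)
        spline_dfree = fit_cox_rcs(cohort, "t_dfree", "e_dfree", "span_score",
                                   config.covariates)
        ref_score = spline_mort.reference_value
        grid = np.arange(ref_score, cohort["span_score"].max(),
                         config.score_grid_step)

        curve_life = lifespan_gain_curve(spline_mort, mort_rates, grid,
                                         config.start_age)

        def dfle_gain_det(hr_row):
            """DFLE gain with CI by HR-endpoint substitution (central rates)."""
            def one(h):
                ex = combined_exit_rates(mort_rates, disease, h, h)
                _, d = disease_free_life_expectancy(ex, disease, config.start_age)
                return d
            base = one(1.0)
            from .lifetable import LEGainEstimate
            return LEGainEstimate("", one(hr_row["hr"]) - base,
                                  one(hr_row["ci_high"]) - base,
                                  one(hr_row["ci_low"]) - base)

        curve_health = lifespan_gain_curve(spline_dfree, mort_rates, grid,
                                           config.start_age, gain_fn=dfle_gain_det)
        _write(curve_life, run_dir / "score_gain_curve_lifespan.csv", manifest, chash)
        _write(curve_health, run_dir / "score_gain_curve_healthspan.csv", manifest, chash)

        # single-behaviour dose-response curves
        singles_life, singles_health = {}, {}
        single_frames = []
        for b, col in (("sleep", "sleep_h_w"), ("mvpa", "mvpa_min_w"),
                       ("dqs", "dqs_w")):
            bgrid = np.linspace(reference[b], mappings[b].floor_high, 80)
            sp_m = fit_cox_rcs(cohort, "followup_y", "death", col,
                               config.covariates)
            sp_d = fit_cox_rcs(cohort, "t_dfree", "e_dfree", col,
                               config.covariates)
            cl = lifespan_gain_curve(sp_m, mort_rates, bgrid, config.start_age)
            ch = lifespan_gain_curve(sp_d, mort_rates, bgrid, config.start_age,
                                     gain_fn=dfle_gain_det)
            singles_life[b], singles_health[b] = cl, ch
            cl2, ch2 = cl.copy(), ch.copy()
            cl2["behaviour"], cl2["outcome"] = b, "lifespan"
            ch2["behaviour"], ch2["outcome"] = b, "healthspan"
            single_frames += [cl2, ch2]
        _write(pd.concat(single_frames, ignore_index=True),
               run_dir / "single_behaviour_gain_curves.csv", manifest, chash)

        mind_life = minimum_dose_table(curve_life, weights, mappings, reference,
                                       ref_score, config.lifespan_targets,
                                       singles_life)
        mind_health = minimum_dose_table(curve_health, weights, mappings,
                                         reference, ref_score,
                                         config.healthspan_targets, singles_health)
        _write(mind_life, run_dir / "min_dose_lifespan.csv", manifest, chash)
        _write(mind_health, run_dir / "min_dose_healthspan.csv", manifest, chash)

        medians = {"sleep": float(cohort["sleep_h_w"].median()),
                   "mvpa": float(cohort["mvpa_min_w"].median()),
                   "dqs": float(cohort["dqs_w"].median())}
        heat = heatmap_grid(spline_mort, mort_rates, mappings, reference,
                            config.start_age, "sleep", "mvpa", medians,
                            n_cells=config.heatmap_cells)
        _write(heat, run_dir / "heatmap_sleep_mvpa.csv", manifest, chash)
        report.log_stage("spanscore", grid_points=len(grid),
                         weights=weights.as_dict())

    # ---- report ---------------------------------------------------------------
    report.warnings = sorted({str(w.message) for w in caught})
    _write(report.to_dict(), run_dir / "run_report.json", manifest, chash)
    return report


def emit_outputs(report: RunReport, directory=None) -> list:
    """Verify the manifest on disk (and return it)."""
    base = Path(directory or report.out_dir)
    for entry in report.manifest:
        path = base / entry["file"]
        if not path.exists():
            raise FileNotFoundError(f"manifest entry missing on disk: {path}")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != entry["sha256"]:
            raise RuntimeError(f"checksum mismatch for {path}")
    return report.manifest
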