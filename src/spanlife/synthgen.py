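"""Synthetic SPAN cohort generator.

The source study is observational — there is no generative model to copy —
so this module defines one with the statistical structure the downstream
analysis assumes, and every distributional choice here is a documented
stand-in, not an estimate of the real cohort:

* exposures drawn through a Gaussian copula with configurable marginals
  (normal sleep, lognormal MVPA for its right skew, normal diet score
  clipped to [0, 100]), parameterised so the implied tertile cut points and
  winsorisation bounds bracket the published ranges;
* all-cause mortality as an exponential-time process whose log hazard is
  baseline + quadratic sleep deviation from a nadir (U-shape) + piecewise
  linear MVPA with an attenuation knot (J-shape) + linear diet effect +
  covariate terms;
* five independent first-incidence disease processes sharing the exposure
  effects at a configurable attenuation, censored by death and follow-up;
* administrative censoring at max follow-up with a staggered-entry fraction
  censored uniformly earlier.

Identical (config, seed) gives a byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .healthspan import CONDITIONS

__all__ = ["SynthConfig", "sample_exposures", "simulate_events",
           "generate_cohort", "COHORT_COLUMNS"]


class ConfigError(ValueError):
    pass


def _default_covariate_spec() -> dict:
    return {
        "age": ("truncnorm", 64.0, 5.8, 45.0, 79.0),
        "sex": ("bernoulli", 0.454),            # 1 = male
        "smoking": ("bernoulli", 0.09),
        "deprivation": ("normal", 0.0, 3.0),
        "alcohol": ("lognormal", 1.8, 0.9),     # units/week
        "screen_h": ("truncnorm", 2.5, 1.2, 0.0, 12.0),
        "lipa_min": ("lognormal", 4.0, 0.4),    # light-intensity PA, min/day
    }


def _default_disease_rates() -> dict:
    # first-incidence rates per person-year at the covariate reference
    return {"cvd": 0.024, "cancer": 0.018, "t2d": 0.007,
            "copd": 0.0035, "dementia": 0.0012}


def _default_covariate_log_hrs() -> dict:
    return {"age": 0.09, "sex": 0.35, "smoking": 0.5}


@dataclass
class SynthConfig:
    """All knobs of the generative model (defaults = the study conditions)."""

    n_participants: int = 10_000
    seed: int = 0
    # exposure marginals
    sleep_mean_sd: tuple = (7.6, 0.93)          # h/day
    mvpa_lognormal_params: tuple = (3.44, 0.70)  # log-scale mean/sd of min/day
    dqs_mean_sd: tuple = (53.75, 8.7)           # 0-100 score
    exposure_correlations: tuple = ((1.0, 0.15, 0.10),
                                    (0.15, 1.0, 0.12),
                                    (0.10, 0.12, 1.0))
    # mortality hazard structure
    sleep_nadir: float = 7.5                    # h/day
    log_hr_sleep_quadratic: float = 0.065       # per (h deviation)^2
    log_hr_mvpa_per_min: float = -0.015         # per min/day up to the knot
    mvpa_knot: float = 50.0                     # min/day, flat beyond
    log_hr_dqs_per_point: float = -0.004        # per DQS point (centred at 50)
    baseline_mortality_rate: float = 0.006      # /person-year at reference
    covariate_log_hrs: dict = field(default_factory=_default_covariate_log_hrs)
    covariate_reference: dict = field(default_factory=lambda: {"age": 64.0})
    # disease processes
    disease_incidence_rates: dict = field(default_factory=_default_disease_rates)
    disease_effect_scale: float = 0.5           # attenuation of exposure effects
    # follow-up / censoring
    max_followup: float = 9.0                   # years
    admin_censor_fraction: float = 0.5          # staggered-entry fraction
    dropout_rate: float = 0.0                   # /person-year, optional
    covariate_spec: dict = field(default_factory=_default_covariate_spec)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.max_followup <= 0:
            raise ConfigError("max_followup must be > 0")
        if not 0 <= self.admin_censor_fraction <= 1:
            raise ConfigError("admin_censor_fraction must lie in [0, 1]")
        if self.baseline_mortality_rate < 0 or self.dropout_rate < 0:
            raise ConfigError("rates must be >= 0")
        if any(r < 0 for r in self.disease_incidence_rates.values()):
            raise ConfigError("disease incidence rates must be >= 0")
        R = self.correlation_matrix()
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigError("exposure correlation matrix is not positive semi-definite")

    def correlation_matrix(self) -> np.ndarray:
        R = np.asarray(self.exposure_correlations, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ConfigError("exposure_correlations must be a symmetric 3x3 "
                              "correlation matrix")
        return R

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sleep_mean_sd"] = list(d["sleep_mean_sd"])
        d["mvpa_lognormal_params"] = list(d["mvpa_lognormal_params"])
        d["dqs_mean_sd"] = list(d["dqs_mean_sd"])
        d["exposure_correlations"] = [list(r) for r in d["exposure_correlations"]]
        d["covariate_spec"] = {k: list(v) for k, v in d["covariate_spec"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("sleep_mean_sd", "mvpa_lognormal_params", "dqs_mean_sd"):
            if key in d:
                d[key] = tuple(d[key])
        if "exposure_correlations" in d:
            d["exposure_correlations"] = tuple(tuple(r) for r in d["exposure_correlations"])
        if "covariate_spec" in d:
            d["covariate_spec"] = {k: tuple(v) for k, v in d["covariate_spec"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "seed" not in d:
            raise ConfigError("config YAML must set a seed")
        return cls.from_dict(d)


COHORT_COLUMNS = (
    ["id", "sleep_h", "mvpa_min", "dqs", "age", "sex", "smoking",
     "deprivation", "alcohol", "screen_h", "lipa_min", "followup_y", "death"]
    + [c for cond in CONDITIONS for c in (f"t_{cond}", f"e_{cond}")]
)


def _sample_covariate(rng: np.random.Generator, spec, n: int) -> np.ndarray:
    dist, *p = spec
    if dist == "normal":
        return rng.normal(p[0], p[1], n)
    if dist == "lognormal":
        return rng.lognormal(p[0], p[1], n)
    if dist == "bernoulli":
        return (rng.random(n) < p[0]).astype(float)
    if dist == "uniform":
        return rng.uniform(p[0], p[1], n)
    if dist == "truncnorm":
        mean, sd, lo, hi = p
        out = rng.normal(mean, sd, n)
        bad = (out < lo) | (out > hi)
        while bad.any():                      # resample tails, keeps the mean
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out
    raise ConfigError(f"unknown covariate distribution {dist!r}")


def sample_exposures(config: SynthConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw correlated sleep / MVPA / DQS exposures plus covariates."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_participants
    R = config.correlation_matrix()
    # PSD guaranteed by config validation; jitter for the Cholesky if singular
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(R + 1e-10 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ L.T

    mu_s, sd_s = config.sleep_mean_sd
    sleep = np.maximum(mu_s + sd_s * z[:, 0], 0.25)
    mu_m, sd_m = config.mvpa_lognormal_params
    mvpa = np.exp(mu_m + sd_m * z[:, 1])
    mu_d, sd_d = config.dqs_mean_sd
    dqs = np.clip(mu_d + sd_d * z[:, 2], 0.0, 100.0)

    out = pd.DataFrame({"id": np.arange(n, dtype=int), "sleep_h": sleep,
                        "mvpa_min": mvpa, "dqs": dqs})
    for name, spec in config.covariate_spec.items():
        out[name] = _sample_covariate(rng, spec, n)
    return out


def _mortality_linear_predictor(config: SynthConfig, df: pd.DataFrame) -> np.ndarray:
    eta = config.log_hr_sleep_quadratic * (df["sleep_h"] - config.sleep_nadir) ** 2
    eta = eta + config.log_hr_mvpa_per_min * np.minimum(df["mvpa_min"], config.mvpa_knot)
    eta = eta + config.log_hr_dqs_per_point * (df["dqs"] - 50.0)
    for cov, beta in config.covariate_log_hrs.items():
        ref = config.covariate_reference.get(cov, 0.0)
        eta = eta + beta * (df[cov] - ref)
    return eta.to_numpy(float)


def simulate_events(exposures: pd.DataFrame, config: SynthConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach death, censoring and per-condition first-event outcomes.

    Event times are exponential given the per-participant hazards (the log
    link makes negative hazards impossible by construction); disease
    processes run independently given the exposures/covariates and are
    censored at the observed (death- or censoring-limited) follow-up.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = len(exposures)
    eta = _mortality_linear_predictor(config, exposures)
    lam_death = config.baseline_mortality_rate * np.exp(eta)

    with np.errstate(divide="ignore"):
        t_death = np.where(lam_death > 0,
                           rng.exponential(1.0, n) / np.where(lam_death > 0, lam_death, 1.0),
                           np.inf)
    censor = np.full(n, config.max_followup)
    staggered = rng.random(n) < config.admin_censor_fraction
    censor[staggered] = rng.uniform(0.5 * config.max_followup,
                                    config.max_followup, int(staggered.sum()))
    if config.dropout_rate > 0:
        censor = np.minimum(censor, rng.exponential(1.0 / config.dropout_rate, n))

    followup = np.minimum(t_death, censor)
    death = (t_death <= censor).astype(int)

    out = exposures.copy()
    out["followup_y"] = followup
    out["death"] = death
    eta_dis = config.disease_effect_scale * eta
    for cond in CONDITIONS:
        base = config.disease_incidence_rates[cond]
        lam = base * np.exp(eta_dis)
        t_c = np.where(lam > 0, rng.exponential(1.0, n) / np.where(lam > 0, lam, 1.0),
                       np.inf)
        out[f"e_{cond}"] = (t_c <= followup).astype(int)
        out[f"t_{cond}"] = np.minimum(t_c, followup)
    return out


def generate_cohort(config: SynthConfig, path=None) -> pd.DataFrame:
    """Exposures + outcomes with the fixed cohort column layout.

    ``path`` (optional) writes the cohort CSV plus a ``<stem>.provenance.json``
    recording the full config.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_exp, rng_ev = (np.random.default_rng(s) for s in ss.spawn(2))
    df = sample_exposures(config, rng_exp)
    df = simulate_events(df, config, rng_ev)
    df = df[COHORT_COLUMNS]
    if path is not None:
        path = Path(path)
        df.to_csv(path, index=False)
        prov = {"config": config.to_dict(), "n_rows": int(len(df)),
                "columns": COHORT_COLUMNS}
        path.with_suffix(".provenance.json").write_text(json.dumps(prov, indent=2))
    return df
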