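"""Exposure cleaning and categorisation.

Winsorisation at the 2.5/97.5 percentiles (or Tukey-fence bounds as the
sensitivity alternative), tertile assignment on the winsorised values, the
27-category joint sleep x MVPA x diet variable, and the cohort exclusion
rules (first-year deaths, pre-existing disease, ...).

Percentile convention: linear interpolation between order statistics
(numpy's default), applied throughout; the winsorisation bounds and tertile
cut points depend on it, so it is fixed here and documented.

Tertile ties: values exactly at a cut point go to the lower tertile.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TertileScheme",
    "ExclusionRules",
    "winsorise",
    "tukey_fence_bounds",
    "assign_tertiles",
    "make_joint_categories",
    "joint_index",
    "joint_triple",
    "apply_exclusions",
]

TERTILE_LABELS = ("low", "medium", "high")
_LEVEL = {"low": 0, "medium": 1, "high": 2}


class PrepError(ValueError):
    pass


@dataclass
class TertileScheme:
    exposure_name: str
    cut_low_med: float
    cut_med_high: float
    observed_min: float
    observed_max: float

    def __post_init__(self) -> None:
        if not self.cut_low_med < self.cut_med_high:
            raise PrepError("tertile cuts must be strictly increasing")
        if not (self.observed_min <= self.cut_low_med
                and self.cut_med_high <= self.observed_max):
            raise PrepError("tertile cuts must lie within the observed range")

    def label(self, values) -> pd.Series:
        """Assign tertile labels; ties at a cut go to the lower tertile."""
        v = pd.Series(values)
        out = pd.Series(
            np.where(v <= self.cut_low_med, "low",
                     np.where(v <= self.cut_med_high, "medium", "high")),
            index=v.index,
        )
        out[v.isna()] = np.nan
        return out


@dataclass
class ExclusionRules:
    """Cohort exclusion switches, applied in a fixed documented order:

    1. data-validity rules (min_valid_days / require_weekend_day),
    2. the death-window rule,
    3. health-status rules (pre-existing disease, poor self-rated health,
       underweight BMI).

    The order affects only the attribution of overlapping exclusions in the
    log, never the final analytic set.
    """

    drop_death_within_years: float = 1.0
    drop_preexisting_disease: bool = False
    drop_poor_self_rated_health: bool = False
    drop_underweight_bmi: bool = False
    min_valid_days: int | None = None
    require_weekend_day: bool = False

    def __post_init__(self) -> None:
        if self.drop_death_within_years < 0:
            raise PrepError("drop_death_within_years must be >= 0")


def winsorise(values, lower_pct: float = 2.5, upper_pct: float = 97.5):
    """Clamp values outside the [lower_pct, upper_pct] percentiles to them.

    Length and order are preserved; NaNs pass through untouched.  Returns a
    pandas Series if given one, else an ndarray.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise PrepError("need 0 <= lower_pct < upper_pct <= 100")
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise PrepError("winsorisation needs at least 2 non-missing values")
    lo, hi = np.percentile(finite, [lower_pct, upper_pct])
    out = np.clip(arr, lo, hi)
    out[np.isnan(arr)] = np.nan
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def tukey_fence_bounds(values, k: float = 1.5) -> tuple[float, float]:
    """(Q1 - k*IQR, Q3 + k*IQR) with linear-interpolation quartiles."""
    if k <= 0:
        raise PrepError("k must be > 0")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 4:
        raise PrepError("Tukey fences need at least 4 non-missing values")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("IQR is zero; Tukey fences collapse to the common value")
        return float(q1), float(q3)
    return float(q1 - k * iqr), float(q3 + k * iqr)


def assign_tertiles(values, exposure_name: str = "exposure"):
    """Tertile scheme + per-row labels, cuts at the 33.33/66.67 percentiles.

    Meant to be called on *winsorised* values, so the scheme's observed
    min/max are the winsorisation bounds (the printed tertile-range endpoints).
    """
    v = pd.Series(values, dtype=float)
    finite = v.dropna()
    if finite.nunique() < 3:
        raise PrepError(f"{exposure_name}: need >= 3 distinct values for tertiles")
    cut1, cut2 = np.percentile(finite, [100 / 3, 200 / 3])
    if cut1 == cut2:
        raise PrepError(f"{exposure_name}: degenerate tertile cuts (massive ties)")
    tied = float(((finite == cut1) | (finite == cut2)).mean())
    if tied > 0.05:
        warnings.warn(f"{exposure_name}: {tied:.1%} of values lie exactly on a "
                      "tertile cut; ties assigned to the lower tertile")
    scheme = TertileScheme(exposure_name, float(cut1), float(cut2),
                           float(finite.min()), float(finite.max()))
    return scheme, scheme.label(v)


def joint_index(sleep_t: str, mvpa_t: str, diet_t: str) -> int:
    """Bijective 1..27 index; 1 = (low, low, low), 27 = (high, high, high).

    Sleep varies slowest, then MVPA, then diet:
    index = 9*sleep + 3*mvpa + diet + 1 on 0-based levels.
    """
    return 9 * _LEVEL[sleep_t] + 3 * _LEVEL[mvpa_t] + _LEVEL[diet_t] + 1


def joint_triple(index: int) -> tuple[str, str, str]:
    """Inverse of :func:`joint_index`."""
    if not 1 <= index <= 27:
        raise PrepError(f"joint category index {index} out of range 1..27")
    z = index - 1
    return (TERTILE_LABELS[z // 9], TERTILE_LABELS[(z // 3) % 3],
            TERTILE_LABELS[z % 3])


def make_joint_categories(sleep_t, mvpa_t, diet_t) -> pd.Series:
    """Per-row 1..27 joint category; rows with any missing label get NaN
    (flagged out of modelling)."""
    s, m, d = (pd.Series(x).astype(object) for x in (sleep_t, mvpa_t, diet_t))
    if not (len(s) == len(m) == len(d)):
        raise PrepError("tertile label series must have equal length")
    out = np.full(len(s), np.nan)
    ok = s.notna().to_numpy() & m.notna().to_numpy() & d.notna().to_numpy()
    for i in np.flatnonzero(ok):
        out[i] = joint_index(s.iloc[i], m.iloc[i], d.iloc[i])
    return pd.Series(out, index=s.index, name="joint_category")


def _need(cohort: pd.DataFrame, col: str, rule: str) -> None:
    if col not in cohort.columns:
        raise PrepError(f"exclusion rule {rule!r} needs missing column {col!r}")


def apply_exclusions(cohort: pd.DataFrame,
                     rules: ExclusionRules) -> tuple[pd.DataFrame, dict]:
    """Apply exclusion rules; returns (filtered cohort, log).

    The log records the rule order, rows removed per rule (attributed to the
    first rule that catches them) and the reconciliation n_in = n_out + sum.
    """
    log: dict = {"n_in": int(len(cohort)), "rules": [], "order": []}
    df = cohort

    def drop(mask: pd.Series, name: str) -> None:
        nonlocal df
        removed = int(mask.sum())
        log["rules"].append({"rule": name, "removed": removed})
        log["order"].append(name)
        df = df[~mask]

    if rules.min_valid_days is not None:
        _need(df, "valid_days", "min_valid_days")
        drop(df["valid_days"] < rules.min_valid_days, "min_valid_days")
    if rules.require_weekend_day:
        _need(df, "has_weekend_day", "require_weekend_day")
        drop(df["has_weekend_day"] == 0, "require_weekend_day")
    if rules.drop_death_within_years > 0:
        for col in ("death", "followup_y"):
            _need(df, col, "drop_death_within_years")
        drop((df["death"] == 1)
             & (df["followup_y"] < rules.drop_death_within_years),
             "drop_death_within_years")
    if rules.drop_preexisting_disease:
        _need(df, "prevalent_disease", "drop_preexisting_disease")
        drop(df["prevalent_disease"] == 1, "drop_preexisting_disease")
    if rules.drop_poor_self_rated_health:
        _need(df, "poor_health", "drop_poor_self_rated_health")
        drop(df["poor_health"] == 1, "drop_poor_self_rated_health")
    if rules.drop_underweight_bmi:
        _need(df, "bmi", "drop_underweight_bmi")
        drop(df["bmi"] < 18.5, "drop_underweight_bmi")

    log["n_out"] = int(len(df))
    log["removed_total"] = log["n_in"] - log["n_out"]
    assert log["removed_total"] == sum(r["removed"] for r in log["rules"])
    log["rules_config"] = asdict(rules)
    return df.copy(), log
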