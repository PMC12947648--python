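"""Composite SPAN score (0-100) and minimum-dose inversion.

Each behaviour contributes a subscore on [0, 100/3], equal nominal weighting,
highest at its theoretically optimal dose:

* sleep      u-shaped, optimum at the mortality-curve nadir (7.5 h/day),
             falling linearly to 0 at both winsorised extremes;
* MVPA       saturating, rising linearly from the winsorised minimum to the
             optimum (default 50 min/day, the dose-response peak) and flat
             beyond;
* diet (DQS) monotone, rising linearly from the winsorised minimum to the
             winsorised maximum.

Piecewise-linear subscores keep the mapping transparent and exactly
invertible, which the minimum-dose decomposition needs.  Hazard-ratio-derived
behaviour weights (from the 27-category joint model) redistribute a composite
score increment across behaviours; inverting each behaviour's mapping from
the 5th-percentile reference upward converts the subscore allocations into
native-unit increments (min/day of sleep and MVPA, DQS points).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import BaselineRates, years_gained
from .prep import joint_triple

__all__ = [
    "ScoreMapping",
    "BehaviourWeights",
    "DoseDecomposition",
    "behaviour_subscore",
    "composite_score",
    "derive_weights",
    "invert_score_increment",
    "lifespan_gain_curve",
    "minimum_dose_table",
    "heatmap_grid",
]

SUBSCORE_MAX = 100.0 / 3.0


class ScoreError(ValueError):
    pass


@dataclass
class ScoreMapping:
    """Piecewise-linear map from a behaviour's native units to [0, 100/3].

    ``floor_low``/``floor_high`` are the winsorised extremes; ``optimal`` the
    dose scoring 100/3.  Shapes: ``u_shaped`` (0 at both extremes),
    ``saturating`` (flat at 100/3 beyond the optimum), ``monotone``
    (optimal == floor_high).
    """

    behaviour: str
    shape: str  # u_shaped | saturating | monotone
    optimal: float
    floor_low: float
    floor_high: float

    def __post_init__(self) -> None:
        if self.shape not in ("u_shaped", "saturating", "monotone"):
            raise ScoreError(f"unknown shape {self.shape!r}")
        if not self.floor_low < self.floor_high:
            raise ScoreError("floor_low must be < floor_high")
        if self.shape == "monotone":
            self.optimal = self.floor_high
        if self.optimal == self.floor_low:
            raise ScoreError("optimal must differ from the floor")
        if not self.floor_low <= self.optimal <= self.floor_high:
            raise ScoreError("optimal must lie within the floors")

    # increasing branch: floor_low -> optimal
    def subscore(self, value):
        v = np.asarray(value, dtype=float)
        up = SUBSCORE_MAX * (v - self.floor_low) / (self.optimal - self.floor_low)
        if self.shape == "u_shaped":
            down = SUBSCORE_MAX * (self.floor_high - v) / (self.floor_high - self.optimal)
            out = np.where(v <= self.optimal, up, down)
        else:  # saturating & monotone: flat at/after the optimum
            out = np.where(v <= self.optimal, up, SUBSCORE_MAX)
        out = np.clip(out, 0.0, SUBSCORE_MAX)
        return float(out) if np.isscalar(value) else out

    def invert_up(self, subscore_target: float) -> float:
        """Value on the increasing branch achieving ``subscore_target``."""
        if not -1e-9 <= subscore_target <= SUBSCORE_MAX + 1e-9:
            raise ScoreError(f"subscore {subscore_target} outside [0, 100/3]")
        s = min(max(subscore_target, 0.0), SUBSCORE_MAX)
        return self.floor_low + s * (self.optimal - self.floor_low) / SUBSCORE_MAX


def behaviour_subscore(value, mapping: ScoreMapping):
    return mapping.subscore(value)


def composite_score(sleep_h, mvpa_min, dqs, mappings: dict):
    """Sum of the three subscores; 0 at all-floor, 100 at all-optimal."""
    for b in ("sleep", "mvpa", "dqs"):
        if b not in mappings:
            raise ScoreError(f"missing score mapping for {b!r}")
    vals = {"sleep": sleep_h, "mvpa": mvpa_min, "dqs": dqs}
    for b, v in vals.items():
        if v is None or (np.isscalar(v) and np.isnan(v)):
            raise ScoreError(f"missing {b} value")
    return (mappings["sleep"].subscore(sleep_h)
            + mappings["mvpa"].subscore(mvpa_min)
            + mappings["dqs"].subscore(dqs))


@dataclass
class BehaviourWeights:
    w_sleep: float
    w_mvpa: float
    w_diet: float

    def __post_init__(self) -> None:
        w = np.array([self.w_sleep, self.w_mvpa, self.w_diet], float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ScoreError("weights must be non-negative and sum to 1")
        # renormalise exactly
        w = w / w.sum()
        self.w_sleep, self.w_mvpa, self.w_diet = map(float, w)

    def as_dict(self) -> dict:
        return {"sleep": self.w_sleep, "mvpa": self.w_mvpa, "dqs": self.w_diet}


def derive_weights(hr_table: pd.DataFrame) -> BehaviourWeights:
    """Behaviour weights from the 27-category HR table.

    A behaviour's marginal span is the mean, over the other two behaviours'
    3x3 tertile combinations, of |log HR(high, ..) - log HR(low, ..)|; the
    three spans are normalised to sum to 1.  Rows with missing HRs drop out
    of the corresponding averages.
    """
    t = hr_table.copy()
    if "category_index" in t.columns and "sleep_t" not in t.columns:
        trip = t["category_index"].astype(int).map(joint_triple)
        t["sleep_t"], t["mvpa_t"], t["diet_t"] = zip(*trip)
    t = t.dropna(subset=["hr"])
    t["log_hr"] = np.log(t["hr"].astype(float))
    axes = {"sleep": ("sleep_t", ["mvpa_t", "diet_t"]),
            "mvpa": ("mvpa_t", ["sleep_t", "diet_t"]),
            "dqs": ("diet_t", ["sleep_t", "mvpa_t"])}
    spans = {}
    for b, (own, others) in axes.items():
        piv = t.pivot_table(index=others, columns=own, values="log_hr")
        if "high" not in piv.columns or "low" not in piv.columns:
            spans[b] = 0.0
            continue
        diffs = (piv["high"] - piv["low"]).dropna().abs()
        spans[b] = float(diffs.mean()) if len(diffs) else 0.0
    total = sum(spans.values())
    if total <= 0:
        warnings.warn("all marginal HR spans are zero; falling back to uniform weights")
        return BehaviourWeights(1 / 3, 1 / 3, 1 / 3)
    return BehaviourWeights(spans["sleep"] / total, spans["mvpa"] / total,
                            spans["dqs"] / total)


@dataclass
class DoseDecomposition:
    delta_score: float
    delta_sleep_min: float      # min/day
    delta_mvpa_min: float       # min/day
    delta_dqs: float            # DQS points
    reference: dict             # behaviour -> reference value (native units)
    overflow_note: str | None = None

    def as_row(self) -> dict:
        return {"delta_score": self.delta_score,
                "delta_sleep_min": self.delta_sleep_min,
                "delta_mvpa_min": self.delta_mvpa_min,
                "delta_dqs": self.delta_dqs}


def invert_score_increment(delta_score: float, weights: BehaviourWeights,
                           mappings: dict, reference: dict) -> DoseDecomposition:
    """Convert a composite-score increment into native-unit increments.

    ``reference`` maps behaviour -> native reference value (the 5th
    percentile of each exposure).  ``delta_score * w_b`` subscore points are
    allocated to behaviour b; allocations beyond a behaviour's remaining
    headroom (its reference subscore to 100/3) are reallocated to the others
    in proportion to their weights, and noted.  Sleep increments are reported
    in min/day (mapping units are h/day).
    """
    if delta_score < 0:
        raise ScoreError("delta_score must be >= 0")
    w = {"sleep": weights.w_sleep, "mvpa": weights.w_mvpa, "dqs": weights.w_diet}
    ref_sub = {b: mappings[b].subscore(reference[b]) for b in w}
    headroom = {b: SUBSCORE_MAX - ref_sub[b] for b in w}
    total_headroom = sum(headroom.values())
    if delta_score > total_headroom + 1e-9:
        raise ScoreError(
            f"delta_score {delta_score:.3g} exceeds total headroom "
            f"{total_headroom:.3g} above the reference point")

    alloc = {b: delta_score * w[b] for b in w}
    note = None
    # reallocate overflow until feasible (at most 3 passes)
    for _ in range(3):
        over = {b: alloc[b] - headroom[b] for b in w if alloc[b] > headroom[b] + 1e-12}
        if not over:
            break
        note = "overflow reallocated: " + ", ".join(
            f"{b} +{v:.3g}" for b, v in over.items())
        excess = sum(over.values())
        for b in over:
            alloc[b] = headroom[b]
        receivers = {b: w[b] for b in w
                     if alloc[b] < headroom[b] - 1e-12}
        wsum = sum(receivers.values())
        for b in receivers:
            share = receivers[b] / wsum if wsum > 0 else 1.0 / len(receivers)
            alloc[b] = min(alloc[b] + excess * share, headroom[b])
    # tiny residual from proportional capping goes to any remaining headroom
    resid = delta_score - sum(alloc.values())
    if resid > 1e-9:
        for b in w:
            room = headroom[b] - alloc[b]
            take = min(room, resid)
            alloc[b] += take
            resid -= take
            if resid <= 1e-12:
                break

    increments = {}
    for b in w:
        v1 = mappings[b].invert_up(ref_sub[b] + alloc[b])
        v0 = mappings[b].invert_up(ref_sub[b])
        increments[b] = v1 - v0
    return DoseDecomposition(
        delta_score=float(delta_score),
        delta_sleep_min=float(increments["sleep"] * 60.0),
        delta_mvpa_min=float(increments["mvpa"]),
        delta_dqs=float(increments["dqs"]),
        reference=dict(reference),
        overflow_note=note,
    )


def lifespan_gain_curve(spline_fit, rates: BaselineRates, grid,
                        start_age: float,
                        gain_fn=None) -> pd.DataFrame:
    """Years gained (with CI) over a grid of scores / exposure values.

    ``spline_fit`` is a survmodel.SplineFit; predictions outside its
    winsorised fitting range are refused.  ``gain_fn(hr_row) -> LEGainEstimate``
    may be supplied to route the same HR curve through the healthspan (DFLE)
    machinery instead of the plain life table.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = spline_fit.support
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ScoreError(
            f"grid [{grid.min():.3g}, {grid.max():.3g}] extends beyond the fitted "
            f"support [{lo:.3g}, {hi:.3g}]; extrapolation refused")
    hr_curve = spline_fit.hazard_ratios(grid)
    rows = []
    for _, r in hr_curve.iterrows():
        if gain_fn is None:
            est = years_gained(r, rates, start_age)
        else:
            est = gain_fn(r)
        rows.append({"x": r["x"], "hr": r["hr"], "hr_lo": r["ci_low"],
                     "hr_hi": r["ci_high"], "years": est.years_gained,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)


def _first_at_least(curve: pd.DataFrame, target: float):
    hit = curve[curve["years"] >= target]
    return None if hit.empty else hit.iloc[0]


def minimum_dose_table(gain_curve: pd.DataFrame, weights: BehaviourWeights,
                       mappings: dict, reference: dict, reference_score: float,
                       targets, single_curves: dict | None = None) -> pd.DataFrame:
    """Minimum combined (and single-behaviour) doses per years-gained target.

    ``gain_curve`` is the composite-score gain curve (columns x, years,
    ci_low, ci_high) on a fine ascending grid.  The first row is the smallest
    score at which the gain CI excludes 0 (ci_low > 0); further rows give, for
    each target, the smallest score whose point gain reaches it, decomposed
    into native-unit increments.  ``single_curves`` maps behaviour ->
    native-unit gain curve; a target unreachable on a behaviour's own curve
    yields a missing entry with the reason recorded.
    """
    curve = gain_curve.sort_values("x").reset_index(drop=True)
    sig = curve[curve["ci_low"] > 0]
    rows = []

    def decompose(score: float) -> dict:
        d = invert_score_increment(max(score - reference_score, 0.0),
                                   weights, mappings, reference)
        return d.as_row()

    def single(target: float) -> dict:
        out = {}
        for b, bc in (single_curves or {}).items():
            hit = _first_at_least(bc.sort_values("x"), target)
            col = {"sleep": "single_sleep_min", "mvpa": "single_mvpa_min",
                   "dqs": "single_dqs"}[b]
            if hit is None:
                out[col] = np.nan
                out[col + "_note"] = "unreachable in isolation"
            else:
                delta = float(hit["x"]) - float(reference[b])
                out[col] = delta * 60.0 if b == "sleep" else delta
                out[col + "_note"] = ""
        return out

    if not sig.empty:
        first = sig.iloc[0]
        row = {"target_years": float(first["years"]),
               "label": "first significant gain", "reachable": True,
               "years": float(first["years"]), "ci_low": float(first["ci_low"]),
               "ci_high": float(first["ci_high"])}
        row.update(decompose(float(first["x"])))
        row.update(single(float(first["years"])))
        rows.append(row)

    for tgt in targets:
        hit = _first_at_least(curve, tgt)
        if hit is None:
            rows.append({"target_years": float(tgt), "label": f"{tgt:g} years",
                         "reachable": False})
            continue
        row = {"target_years": float(tgt), "label": f"{tgt:g} years",
               "reachable": True, "years": float(hit["years"]),
               "ci_low": float(hit["ci_low"]), "ci_high": float(hit["ci_high"])}
        row.update(decompose(float(hit["x"])))
        row.update(single(tgt))
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_grid(score_spline, rates: BaselineRates, mappings: dict,
                 reference: dict, start_age: float,
                 behaviour_x: str, behaviour_y: str, fixed: dict,
                 n_cells: int = 15) -> pd.DataFrame:
    """Long-format years-gained grid over two behaviours, third held fixed.

    Cells are evaluated through the composite score: score(x, y, fixed third)
    mapped through the score dose-response spline, years gained versus the
    reference corner (5th-percentile x and y).  The reference corner is 0 by
    construction.
    """
    mx, my = mappings[behaviour_x], mappings[behaviour_y]
    gx = np.linspace(mx.floor_low, mx.floor_high, n_cells)
    gy = np.linspace(my.floor_low, my.floor_high, n_cells)
    third = ({"sleep", "mvpa", "dqs"} - {behaviour_x, behaviour_y}).pop()

    def score_at(vx, vy):
        vals = {behaviour_x: vx, behaviour_y: vy, third: fixed[third]}
        return composite_score(vals["sleep"], vals["mvpa"], vals["dqs"], mappings)

    ref_score = score_at(reference[behaviour_x], reference[behaviour_y])
    lo, hi = score_spline.support
    rows = []
    for vx in gx:
        for vy in gy:
            s = float(np.clip(score_at(vx, vy), lo, hi))
            sr = float(np.clip(ref_score, lo, hi))
            hr_s = score_spline.hazard_ratios([s]).iloc[0]
            hr_r = score_spline.hazard_ratios([sr]).iloc[0]
            e_s = years_gained(hr_s, rates, start_age)
            e_r = years_gained(hr_r, rates, start_age)
            rows.append({behaviour_x: vx, behaviour_y: vy, third: fixed[third],
                         "score": s, "years_gained": e_s.years_gained - e_r.years_gained})
    return pd.DataFrame(rows)
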