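"""Composite score algebra, weight derivation, dose inversion, minimum-dose
tables and the heatmap grid."""

import numpy as np
import pandas as pd
import pytest

from spanlife.lifetable import BaselineRates
from spanlife.prep import joint_triple
from spanlife.spanscore import (SUBSCORE_MAX, BehaviourWeights, ScoreError,
                                ScoreMapping, behaviour_subscore,
                                composite_score, derive_weights, heatmap_grid,
                                invert_score_increment, lifespan_gain_curve,
                                minimum_dose_table)
from spanlife.survmodel import SplineFit


def default_mappings():
    return {"sleep": ScoreMapping("sleep", "u_shaped", 7.5, 4.8, 9.4),
            "mvpa": ScoreMapping("mvpa", "saturating", 50.0, 5.0, 103.0),
            "dqs": ScoreMapping("dqs", "monotone", 72.5, 32.5, 72.5)}


def linear_spline(log_hr_per_unit, reference, support):
    """SplineFit with an exactly linear log-HR and zero variance — a
    deterministic stand-in for a fitted dose-response curve."""
    knots = np.linspace(support[0], support[1], 4)
    beta = np.array([log_hr_per_unit, 0.0, 0.0])
    return SplineFit("x", knots, beta, np.zeros((3, 3)), reference,
                     support, n_events=1)


class TestSubscores:
    def test_optimum_scores_exactly_one_third(self):
        maps = default_mappings()
        assert behaviour_subscore(7.5, maps["sleep"]) == pytest.approx(SUBSCORE_MAX)
        assert behaviour_subscore(50.0, maps["mvpa"]) == pytest.approx(SUBSCORE_MAX)
        assert behaviour_subscore(72.5, maps["dqs"]) == pytest.approx(SUBSCORE_MAX)

    def test_floors_score_zero(self):
        maps = default_mappings()
        assert behaviour_subscore(4.8, maps["sleep"]) == 0.0
        assert behaviour_subscore(9.4, maps["sleep"]) == 0.0
        assert behaviour_subscore(5.0, maps["mvpa"]) == 0.0
        assert behaviour_subscore(32.5, maps["dqs"]) == 0.0

    def test_symmetric_u_shape(self):
        sym = ScoreMapping("sleep", "u_shaped", 7.5, 5.5, 9.5)
        assert behaviour_subscore(7.0, sym) == pytest.approx(
            behaviour_subscore(8.0, sym))

    def test_saturating_flat_beyond_optimum(self):
        m = default_mappings()["mvpa"]
        assert behaviour_subscore(80.0, m) == SUBSCORE_MAX
        assert behaviour_subscore(200.0, m) == SUBSCORE_MAX  # clipped

    def test_degenerate_mapping_rejected(self):
        with pytest.raises(ScoreError):
            ScoreMapping("x", "monotone", 5.0, 5.0, 5.0)


class TestComposite:
    def test_endpoints_exact(self):
        maps = default_mappings()
        assert composite_score(7.5, 50.0, 72.5, maps) == pytest.approx(100.0)
        assert composite_score(4.8, 5.0, 32.5, maps) == pytest.approx(0.0)

    def test_one_optimal_two_floor(self):
        maps = default_mappings()
        assert composite_score(7.5, 5.0, 32.5, maps) == pytest.approx(100 / 3)

    def test_missing_value_rejected(self):
        with pytest.raises(ScoreError):
            composite_score(np.nan, 50.0, 60.0, default_mappings())


class TestWeights:
    @staticmethod
    def table_from_log_spans(s_span, m_span, d_span):
        rows = []
        for idx in range(1, 28):
            s, m, d = joint_triple(idx)
            lvl = {"low": 0.0, "medium": 0.5, "high": 1.0}
            log_hr = (s_span * lvl[s] + m_span * lvl[m] + d_span * lvl[d])
            rows.append({"category_index": idx, "sleep_t": s, "mvpa_t": m,
                         "diet_t": d, "hr": np.exp(log_hr)})
        return pd.DataFrame(rows)

    def test_single_behaviour_table_degenerate(self):
        w = derive_weights(self.table_from_log_spans(0.0, 0.7, 0.0))
        assert (w.w_sleep, w.w_mvpa, w.w_diet) == (0.0, 1.0, 0.0)

    def test_symmetric_table_uniform(self):
        w = derive_weights(self.table_from_log_spans(0.4, 0.4, 0.4))
        assert w.w_sleep == pytest.approx(1 / 3)

    def test_constructed_spans_normalised(self):
        w = derive_weights(self.table_from_log_spans(0.2, 0.6, 0.2))
        assert (w.w_sleep, w.w_mvpa, w.w_diet) == pytest.approx((0.2, 0.6, 0.2))

    def test_flat_table_falls_back_uniform(self):
        with pytest.warns(UserWarning, match="uniform"):
            w = derive_weights(self.table_from_log_spans(0.0, 0.0, 0.0))
        assert w.w_mvpa == pytest.approx(1 / 3)

    def test_simplex_enforced(self):
        with pytest.raises(ScoreError):
            BehaviourWeights(0.5, 0.5, 0.5)


class TestInversion:
    reference = {"sleep": 5.5, "mvpa": 7.3, "dqs": 36.9}

    def test_zero_increment_zero_doses(self):
        d = invert_score_increment(0.0, BehaviourWeights(1/3, 1/3, 1/3),
                                   default_mappings(), self.reference)
        assert (d.delta_sleep_min, d.delta_mvpa_min, d.delta_dqs) == (0, 0, 0)

    def test_single_weight_moves_single_behaviour(self):
        d = invert_score_increment(5.0, BehaviourWeights(1.0, 0.0, 0.0),
                                   default_mappings(), self.reference)
        assert d.delta_sleep_min > 0
        assert d.delta_mvpa_min == 0 and d.delta_dqs == 0

    def test_round_trip_identity(self):
        maps = default_mappings()
        rng = np.random.default_rng(11)
        for _ in range(200):
            raw = rng.dirichlet([1, 1, 1])
            w = BehaviourWeights(*raw)
            delta = float(rng.uniform(0, 40))
            d = invert_score_increment(delta, w, maps, self.reference)
            before = composite_score(self.reference["sleep"],
                                     self.reference["mvpa"],
                                     self.reference["dqs"], maps)
            after = composite_score(self.reference["sleep"] + d.delta_sleep_min / 60,
                                    self.reference["mvpa"] + d.delta_mvpa_min,
                                    self.reference["dqs"] + d.delta_dqs, maps)
            assert after - before == pytest.approx(delta, abs=1e-6)

    def test_overflow_reallocated_and_noted(self):
        # all weight on diet, but diet headroom above the reference is small
        ref = {"sleep": 5.5, "mvpa": 7.3, "dqs": 70.0}
        d = invert_score_increment(10.0, BehaviourWeights(0.0, 0.0, 1.0),
                                   default_mappings(), ref)
        assert d.overflow_note is not None
        assert d.delta_sleep_min > 0 or d.delta_mvpa_min > 0

    def test_exceeding_total_headroom_rejected(self):
        ref = {"sleep": 7.4, "mvpa": 49.0, "dqs": 72.0}  # near-optimal already
        with pytest.raises(ScoreError, match="headroom"):
            invert_score_increment(50.0, BehaviourWeights(1/3, 1/3, 1/3),
                                   default_mappings(), ref)


class TestGainCurve:
    rates = BaselineRates([64.0], [np.inf], [0.05])

    def test_reference_gain_zero_with_degenerate_ci(self):
        sp = linear_spline(-0.02, reference=10.0, support=(0.0, 100.0))
        curve = lifespan_gain_curve(sp, self.rates, [10.0, 30.0], 64.0)
        first = curve.iloc[0]
        assert first.years == 0.0 == first.ci_low == first.ci_high

    def test_monotone_hr_gives_monotone_gains(self):
        sp = linear_spline(-0.02, reference=0.0, support=(0.0, 100.0))
        curve = lifespan_gain_curve(sp, self.rates, np.linspace(0, 90, 10), 64.0)
        assert (np.diff(curve.years) > 0).all()

    def test_extrapolation_refused(self):
        sp = linear_spline(-0.02, reference=10.0, support=(0.0, 100.0))
        with pytest.raises(ScoreError, match="support"):
            lifespan_gain_curve(sp, self.rates, [50.0, 150.0], 64.0)


class TestMinimumDose:
    rates = BaselineRates([64.0], [np.inf], [0.05])
    weights = BehaviourWeights(1/3, 1/3, 1/3)
    reference = {"sleep": 5.5, "mvpa": 7.3, "dqs": 36.9}

    @staticmethod
    def curve(grid, years, half_width):
        return pd.DataFrame({"x": grid, "years": years,
                             "ci_low": years - half_width,
                             "ci_high": years + half_width})

    def test_flat_null_curve_yields_no_reachable_rows(self):
        grid = np.arange(0, 50, 0.5)
        curve = self.curve(grid, np.zeros_like(grid), 0.5)
        out = minimum_dose_table(curve, self.weights, default_mappings(),
                                 self.reference, 0.0, targets=[1, 2])
        assert out[out.get("reachable", pd.Series(dtype=bool)) == True].empty  # noqa: E712

    def test_first_row_is_first_significant_score(self):
        grid = np.arange(0.0, 50.0, 0.5)
        years = 0.2 * grid            # 5 years at score 25
        curve = self.curve(grid, years, half_width=2.0)  # significant once y>2
        out = minimum_dose_table(curve, self.weights, default_mappings(),
                                 self.reference, 0.0, targets=[5])
        first = out.iloc[0]
        assert first.label == "first significant gain"
        # ci_low = 0.2x - 2 > 0 first at x = 10.5 on the 0.5 grid
        assert first.delta_score == pytest.approx(10.5)
        row5 = out[out.label == "5 years"].iloc[0]
        assert row5.delta_score == pytest.approx(25.0)

    def test_targets_ascending_doses_nondecreasing(self):
        grid = np.arange(0.0, 60.0, 0.5)
        curve = self.curve(grid, 0.15 * grid, 0.5)
        out = minimum_dose_table(curve, self.weights, default_mappings(),
                                 self.reference, 0.0, targets=[1, 2, 3, 4, 5])
        tgt = out[out.label != "first significant gain"]
        assert (np.diff(tgt.delta_score) >= 0).all()

    def test_unreachable_target_flagged(self):
        grid = np.arange(0.0, 30.0, 0.5)
        curve = self.curve(grid, 0.05 * grid, 0.1)   # max gain 1.5 y
        out = minimum_dose_table(curve, self.weights, default_mappings(),
                                 self.reference, 0.0, targets=[1, 10])
        assert bool(out[out.label == "10 years"].iloc[0].reachable) is False

    def test_single_behaviour_columns_and_missing_reason(self):
        grid = np.arange(0.0, 60.0, 0.5)
        curve = self.curve(grid, 0.2 * grid, 0.5)
        # sleep alone can reach 2y (at value 7.5 vs ref 5.5); mvpa cannot
        singles = {
            "sleep": pd.DataFrame({"x": np.linspace(5.5, 9.4, 40),
                                   "years": np.linspace(0, 4, 40)}),
            "mvpa": pd.DataFrame({"x": np.linspace(7.3, 103, 40),
                                  "years": np.linspace(0, 0.5, 40)}),
        }
        out = minimum_dose_table(curve, self.weights, default_mappings(),
                                 self.reference, 0.0, targets=[2],
                                 single_curves=singles)
        row = out[out.label == "2 years"].iloc[0]
        assert row.single_sleep_min > 0
        assert np.isnan(row.single_mvpa_min)
        assert row.single_mvpa_min_note == "unreachable in isolation"


class TestHeatmap:
    def test_reference_corner_zero_and_monotone_rows(self):
        rates = BaselineRates([64.0], [np.inf], [0.05])
        maps = default_mappings()
        sp = linear_spline(-0.02, reference=0.0, support=(0.0, 100.0))
        ref = {"sleep": 4.8, "mvpa": 5.0, "dqs": 36.9}
        grid = heatmap_grid(sp, rates, maps, ref, 64.0, "dqs", "mvpa",
                            fixed={"sleep": 7.0}, n_cells=5)
        corner = grid[(grid.dqs == 32.5) & (grid.mvpa == 5.0)]
        # reference corner uses the 5th-pct reference values; evaluate there
        ref_cell = grid.iloc[(grid.dqs - ref["dqs"]).abs().argsort()].iloc[0]
        assert len(grid) == 25
        # monotone behaviours (dqs up, mvpa up to optimum) -> gains rise along rows
        for _, block in grid.groupby("mvpa"):
            b = block.sort_values("dqs")
            assert (np.diff(b.years_gained) >= -1e-9).all()
        assert corner.years_gained.iloc[0] <= grid.years_gained.max()
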