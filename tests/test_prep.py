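"""Winsorisation, Tukey fences, tertiles, joint categories, exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spanlife.prep import (ExclusionRules, PrepError, apply_exclusions,
                           assign_tertiles, joint_index, joint_triple,
                           make_joint_categories, tukey_fence_bounds,
                           winsorise)


class TestWinsorise:
    def test_percentile_formula_on_1_to_100(self):
        # linear-interpolation percentiles of 1..100: 2.5% -> 3.475, 97.5% -> 97.525
        out = winsorise(np.arange(1.0, 101.0), 2.5, 97.5)
        assert out.min() == pytest.approx(3.475)
        assert out.max() == pytest.approx(97.525)
        assert len(out) == 100

    def test_full_range_is_identity(self):
        x = np.array([5.0, 1.0, 9.0, 3.0])
        np.testing.assert_array_equal(winsorise(x, 0, 100), x)

    def test_nearly_idempotent(self):
        # exact idempotence cannot hold under interpolated percentiles (the
        # clamped mass shifts the interpolated bound by at most one
        # order-statistic gap); re-winsorising must move nothing by more
        # than that gap
        rng = np.random.default_rng(0)
        x = rng.lognormal(3, 1, 500)
        once = winsorise(x)
        twice = winsorise(once)
        gap = np.max(np.diff(np.sort(once)))
        assert np.max(np.abs(twice - once)) <= gap
        assert (twice == once).mean() > 0.9

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_preserves_length_order_and_bounds(self, xs):
        x = np.array(xs)
        out = winsorise(x, 10, 90)
        assert out.shape == x.shape
        # monotone order preservation
        order = np.argsort(x, kind="stable")
        assert (np.diff(out[order]) >= 0).all()
        lo, hi = np.percentile(x, [10, 90])
        assert out.min() >= lo - 1e-9 and out.max() <= hi + 1e-9

    def test_nan_passthrough_and_series_roundtrip(self):
        s = pd.Series([1.0, np.nan, 100.0, 50.0], index=[9, 8, 7, 6])
        out = winsorise(s, 25, 75)
        assert isinstance(out, pd.Series)
        assert list(out.index) == [9, 8, 7, 6]
        assert np.isnan(out.iloc[1])

    def test_too_few_values_rejected(self):
        with pytest.raises(PrepError):
            winsorise([1.0])

    def test_identical_values_unchanged(self):
        out = winsorise(np.full(10, 3.0))
        np.testing.assert_array_equal(out, np.full(10, 3.0))


class TestTukey:
    def test_quartile_formula_on_1_to_11(self):
        # Q1=3.5, Q3=8.5 under linear interpolation -> bounds (-4.0, 16.0)
        lo, hi = tukey_fence_bounds(np.arange(1.0, 12.0), k=1.5)
        assert (lo, hi) == pytest.approx((-4.0, 16.0))

    def test_symmetric_data_symmetric_about_median(self):
        x = np.array([-4, -2, -1, 0, 1, 2, 4], dtype=float)
        lo, hi = tukey_fence_bounds(x)
        assert lo == pytest.approx(-hi)

    def test_zero_iqr_warns_and_collapses(self):
        with pytest.warns(UserWarning, match="IQR"):
            lo, hi = tukey_fence_bounds(np.array([5.0] * 10))
        assert lo == hi == 5.0

    def test_bad_inputs(self):
        with pytest.raises(PrepError):
            tukey_fence_bounds([1.0, 2.0, 3.0])
        with pytest.raises(PrepError):
            tukey_fence_bounds(np.arange(10.0), k=0)


class TestTertiles:
    def test_equal_thirds_on_1_to_9(self):
        scheme, labels = assign_tertiles(np.arange(1.0, 10.0))
        assert scheme.cut_low_med == pytest.approx(11 / 3)
        assert scheme.cut_med_high == pytest.approx(19 / 3)
        assert list(labels) == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3

    def test_three_distinct_values_one_each(self):
        _, labels = assign_tertiles(np.array([1.0, 2.0, 3.0]))
        assert sorted(labels) == ["high", "low", "medium"]

    def test_constant_series_rejected(self):
        with pytest.raises(PrepError):
            assign_tertiles(np.full(30, 2.0))

    def test_group_sizes_balanced_for_distinct_values(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=301)
        _, labels = assign_tertiles(x)
        counts = labels.value_counts()
        assert counts.max() - counts.min() <= 1

    def test_ties_go_to_lower_tertile(self):
        # heavy mass exactly on the lower cut (cut1 = 2 here)
        x = np.repeat([1.0, 2.0, 4.0, 5.0], [2, 5, 3, 2])
        with pytest.warns(UserWarning, match="cut"):
            scheme, labels = assign_tertiles(x)
        assert scheme.cut_low_med == 2.0
        assert (labels[x == 2.0] == "low").all()
        assert (labels[x == 4.0] == "medium").all()


class TestJointCategories:
    def test_reference_and_extremes(self):
        assert joint_index("low", "low", "low") == 1
        assert joint_index("high", "high", "high") == 27

    def test_bijection_round_trip(self):
        seen = set()
        for s in ("low", "medium", "high"):
            for m in ("low", "medium", "high"):
                for d in ("low", "medium", "high"):
                    idx = joint_index(s, m, d)
                    assert joint_triple(idx) == (s, m, d)
                    seen.add(idx)
        assert seen == set(range(1, 28))

    def test_full_factorial_covers_27(self):
        combos = [(s, m, d)
                  for s in ("low", "medium", "high")
                  for m in ("low", "medium", "high")
                  for d in ("low", "medium", "high")]
        out = make_joint_categories(*map(pd.Series, zip(*combos)))
        assert sorted(out.astype(int)) == list(range(1, 28))

    def test_missing_label_flagged_not_modelled(self):
        out = make_joint_categories(pd.Series(["low", None]),
                                    pd.Series(["low", "high"]),
                                    pd.Series(["low", "high"]))
        assert out.iloc[0] == 1 and np.isnan(out.iloc[1])


class TestExclusions:
    @staticmethod
    def toy_cohort():
        # 10 rows: ids 0,1 die in year one; id 1 also has pre-existing disease
        df = pd.DataFrame({
            "death": [1, 1, 0, 0, 0, 0, 0, 1, 0, 0],
            "followup_y": [0.5, 0.9, 5, 5, 5, 5, 5, 4.0, 5, 5],
            "prevalent_disease": [0, 1, 0, 0, 1, 0, 0, 0, 0, 0],
        })
        return df

    def test_first_year_death_removed(self):
        out, log = apply_exclusions(self.toy_cohort(),
                                    ExclusionRules(drop_death_within_years=1))
        assert len(out) == 8
        assert log["rules"][0] == {"rule": "drop_death_within_years", "removed": 2}

    def test_all_rules_off_is_identity(self):
        cohort = self.toy_cohort()
        out, log = apply_exclusions(cohort, ExclusionRules(drop_death_within_years=0))
        pd.testing.assert_frame_equal(out, cohort)
        assert log["removed_total"] == 0

    def test_overlap_attribution_reconciles(self):
        # 2 first-year deaths + 2 prevalent, one overlapping -> 10-2-1 = 7 rows
        out, log = apply_exclusions(
            self.toy_cohort(),
            ExclusionRules(drop_death_within_years=1, drop_preexisting_disease=True))
        assert len(out) == 7
        removed = {r["rule"]: r["removed"] for r in log["rules"]}
        assert removed == {"drop_death_within_years": 2,
                           "drop_preexisting_disease": 1}
        assert log["n_in"] - log["n_out"] == sum(removed.values())

    def test_missing_column_named_in_error(self):
        with pytest.raises(PrepError, match="bmi"):
            apply_exclusions(self.toy_cohort(),
                             ExclusionRules(drop_underweight_bmi=True))
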