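"""Chiang life-table construction, HR adjustment and years-gained logic."""

import numpy as np
import pandas as pd
import pytest

from spanlife.lifetable import (BaselineRates, LifeTableError, RADIX,
                                adjust_rates, build_life_table,
                                life_expectancy_from_rates,
                                sex_stratified_gains, years_gained)

from conftest import random_rate_schedule


def chiang_oracle(m, width, a=0.5):
    """Independent step-by-step recursion, written directly from the
    definitions (q from m, l recursion, L person-years, e = T/l)."""
    k = len(m)
    q = [width[i] * m[i] / (1 + width[i] * (1 - a) * m[i]) for i in range(k - 1)] + [1.0]
    l = [1.0]
    for i in range(k - 1):
        l.append(l[i] * (1 - q[i]))
    L = [width[i] * (l[i] - q[i] * l[i] + a * q[i] * l[i]) for i in range(k - 1)]
    L.append(l[-1] / m[-1])
    T = [sum(L[i:]) for i in range(k)]
    return [T[i] / l[i] for i in range(k)]


def open_interval(m):
    return BaselineRates([64.0], [np.inf], [m])


class TestConstruction:
    def test_single_open_interval_is_inverse_rate(self):
        table = build_life_table(open_interval(0.05))
        assert table["e"].iloc[0] == pytest.approx(20.0, abs=1e-12)

    def test_matches_stepwise_recursion_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            rates = random_rate_schedule(rng)
            table = build_life_table(rates)
            expect = chiang_oracle(rates.m, rates.width)
            np.testing.assert_allclose(table["e"].to_numpy(), expect, atol=1e-10)

    def test_two_interval_hand_case(self):
        # m = 0.1 (1y closed) then 0.1 open: constant hazard, e0 = 1/m = 10
        rates = BaselineRates([60.0, 61.0], [1.0, np.inf], [0.1, 0.1])
        assert build_life_table(rates)["e"].iloc[0] == pytest.approx(10.0, rel=1e-12)

    def test_chiang_identities_hold_exactly(self, national_rates):
        t = build_life_table(national_rates)
        w, a = t["width"].to_numpy(), 0.5
        closed = np.isfinite(w)
        q_expect = w[closed] * t["m"][closed] / (1 + w[closed] * (1 - a) * t["m"][closed])
        np.testing.assert_allclose(t["q"][closed], q_expect, rtol=0, atol=1e-14)
        np.testing.assert_allclose(t["l"].to_numpy()[1:],
                                   (t["l"] * (1 - t["q"])).to_numpy()[:-1], rtol=1e-14)
        np.testing.assert_allclose(t["T"].to_numpy()[:-1],
                                   t["L"].to_numpy()[:-1] + t["T"].to_numpy()[1:],
                                   rtol=1e-14)
        np.testing.assert_allclose(t["e"], t["T"] / t["l"], rtol=1e-14)
        assert t["l"].iloc[0] == RADIX
        assert (np.diff(t["l"]) <= 0).all() and (np.diff(t["T"]) <= 0).all()

    def test_doubling_rates_lowers_expectancy(self, national_rates):
        e1 = build_life_table(national_rates)["e"].iloc[0]
        e2 = build_life_table(national_rates.with_rates(2 * national_rates.m))["e"].iloc[0]
        assert e2 < e1

    def test_vectorised_core_agrees_with_table(self, national_rates):
        e_vec = life_expectancy_from_rates(national_rates.m, national_rates.width)
        assert e_vec == pytest.approx(build_life_table(national_rates)["e"].iloc[0])

    def test_zero_open_rate_rejected(self):
        with pytest.raises(LifeTableError, match="open interval"):
            build_life_table(open_interval(0.0))

    @pytest.mark.parametrize("bad", [
        dict(age_start=[60, 59], width=[1, np.inf], m=[0.1, 0.1]),
        dict(age_start=[60, 62], width=[1, np.inf], m=[0.1, 0.1]),
        dict(age_start=[60, 61], width=[1, 1.0], m=[0.1, 0.1]),
        dict(age_start=[60, 61], width=[1, np.inf], m=[-0.1, 0.1]),
    ])
    def test_invalid_schedules_rejected(self, bad):
        with pytest.raises(LifeTableError):
            BaselineRates(**bad)

    def test_start_age_must_be_boundary(self, national_rates):
        with pytest.raises(LifeTableError, match="boundary"):
            national_rates.from_age(64.5)


class TestAdjustment:
    def test_hr_one_is_identity(self, national_rates):
        out = adjust_rates(national_rates, 1.0)
        np.testing.assert_array_equal(out.m, national_rates.m)

    def test_hr_two_doubles(self, national_rates):
        out = adjust_rates(national_rates, 2.0)
        np.testing.assert_allclose(out.m, 2 * national_rates.m)

    def test_population_calibration_reproduces_baseline(self, national_rates):
        p, hrs = [1 / 3, 1 / 3, 1 / 3], [0.5, 1.0, 1.5]
        adjusted = [adjust_rates(national_rates, h, "population",
                                 prevalences=p, hrs_all=hrs).m for h in hrs]
        weighted = sum(pi * mi for pi, mi in zip(p, adjusted))
        np.testing.assert_allclose(weighted, national_rates.m, rtol=1e-12)

    def test_population_mode_needs_prevalences(self, national_rates):
        with pytest.raises(LifeTableError):
            adjust_rates(national_rates, 1.2, "population")


class TestYearsGained:
    def test_null_hr_gains_zero(self, national_rates):
        est = years_gained({"hr": 1.0, "ci_low": 1.0, "ci_high": 1.0},
                           national_rates, 64.0)
        assert est.years_gained == 0.0 == est.ci_low == est.ci_high

    def test_halved_hazard_closed_form(self):
        est = years_gained({"hr": 0.5, "ci_low": 0.5, "ci_high": 0.5},
                           open_interval(0.05), 64.0)
        assert est.years_gained == pytest.approx(1 / 0.025 - 1 / 0.05, rel=1e-12)

    def test_strictly_decreasing_in_hr(self, national_rates):
        gains = [years_gained({"hr": h, "ci_low": h, "ci_high": h},
                              national_rates, 64.0).years_gained
                 for h in [0.5, 0.8, 1.0, 1.3, 2.0]]
        assert all(a > b for a, b in zip(gains, gains[1:]))
        assert gains[2] == 0.0

    def test_ci_ordering_guaranteed(self, national_rates):
        est = years_gained({"hr": 0.8, "ci_low": 0.6, "ci_high": 1.1},
                           national_rates, 64.0)
        assert est.ci_low <= est.years_gained <= est.ci_high
        assert est.ci_low < 0 < est.ci_high  # CI crossing 1 crosses 0 gain


class TestStratified:
    @staticmethod
    def _hr_frame(hr):
        return pd.DataFrame([{"label": "cat", "hr": hr, "ci_low": hr * 0.9,
                              "ci_high": hr * 1.1}])

    def test_identical_strata_identical_gains(self, national_rates):
        out = sex_stratified_gains(
            {"male": self._hr_frame(0.7), "female": self._hr_frame(0.7)},
            {"male": national_rates, "female": national_rates}, 64.0)
        g = out.set_index("stratum")["years_gained"]
        assert g["male"] == pytest.approx(g["female"])

    def test_higher_mortality_stratum_gains_more(self):
        male = open_interval(0.06)
        female = open_interval(0.04)
        out = sex_stratified_gains(
            {"male": self._hr_frame(0.5), "female": self._hr_frame(0.5)},
            {"male": male, "female": female}, 64.0)
        g = out.set_index("stratum")["years_gained"]
        # closed form: gain = (1/hr - 1)/m, so for hr<1 the *lower*-mortality
        # stratum gains more absolute years in the single-interval case
        assert g["male"] == pytest.approx(1 / 0.03 - 1 / 0.06)
        assert g["female"] == pytest.approx(1 / 0.02 - 1 / 0.04)
        assert g["female"] > g["male"]

    def test_null_stratum_zero(self, national_rates):
        out = sex_stratified_gains(
            {"male": self._hr_frame(1.0)}, {"male": national_rates}, 64.0)
        assert out["years_gained"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_stratum_mismatch_rejected(self, national_rates):
        with pytest.raises(LifeTableError, match="mismatch"):
            sex_stratified_gains({"male": self._hr_frame(1.0)},
                                 {"female": national_rates}, 64.0)
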