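"""Period life tables and hazard-ratio-adjusted life expectancy.

The lifespan side of the analysis: a conventional (Chiang) period life table
built from age-specific all-cause mortality rates ``m(x)``, with the rates
optionally multiplied by a fitted hazard ratio before the table is built.
Years of life expectancy gained for an exposure category are then the
difference in ``e(start_age)`` between the category's adjusted table and the
reference table, with confidence limits obtained by substituting the HR
confidence limits (the mapping hr -> e is monotone decreasing, so the CI
endpoints map to LE endpoints directly).

Conventions
-----------
* Closed intervals use the mid-interval separation factor a = 0.5, so the
  death probability is  q = w*m / (1 + w*(1-a)*m).
* The final interval is open-ended; its person-years are L = l/m and it
  requires m > 0.
* Radix 100,000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BaselineRates",
    "LEGainEstimate",
    "life_expectancy_from_rates",
    "build_life_table",
    "adjust_rates",
    "years_gained",
    "sex_stratified_gains",
]

RADIX = 100_000.0


class LifeTableError(ValueError):
    """Invalid rate schedule or life-table request."""


@dataclass
class BaselineRates:
    """Age-specific mortality (or exit) rate schedule.

    Parameters
    ----------
    age_start : array of interval start ages (years), strictly increasing and
        contiguous: ``age_start[i+1] == age_start[i] + width[i]``.
    width : interval widths in years; the final entry must be ``inf``
        (open-ended interval).
    m : rate per person-year in each interval, all >= 0.
    sex : optional stratum label ("male"/"female"/None).
    """

    age_start: np.ndarray
    width: np.ndarray
    m: np.ndarray
    sex: str | None = None

    def __post_init__(self) -> None:
        self.age_start = np.asarray(self.age_start, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if not (self.age_start.shape == self.width.shape == self.m.shape):
            raise LifeTableError("age_start, width and m must have equal length")
        if self.age_start.size == 0:
            raise LifeTableError("empty rate schedule")
        if np.any(np.diff(self.age_start) <= 0):
            raise LifeTableError("age_start must be strictly increasing")
        closed = self.width[:-1]
        if self.age_start.size > 1 and not np.allclose(
            self.age_start[1:], self.age_start[:-1] + closed
        ):
            raise LifeTableError("intervals must be contiguous")
        if not math.isinf(self.width[-1]):
            raise LifeTableError("final interval must be open-ended (width=inf)")
        if np.any(self.m < 0) or not np.all(np.isfinite(self.m)):
            raise LifeTableError("rates must be finite and >= 0")

    # -- convenience -------------------------------------------------------

    def from_age(self, start_age: float) -> "BaselineRates":
        """Truncate the schedule to intervals at or above ``start_age``.

        ``start_age`` must coincide with an interval boundary.
        """
        idx = np.flatnonzero(np.isclose(self.age_start, start_age))
        if idx.size == 0:
            raise LifeTableError(
                f"start_age {start_age} is not an interval boundary of the schedule"
            )
        i = int(idx[0])
        return BaselineRates(self.age_start[i:], self.width[i:], self.m[i:], self.sex)

    def with_rates(self, m: np.ndarray) -> "BaselineRates":
        return BaselineRates(self.age_start.copy(), self.width.copy(), np.asarray(m, float), self.sex)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_start": self.age_start, "width": self.width, "m": self.m,
             "sex": self.sex if self.sex is not None else ""}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sex: str | None = None) -> "BaselineRates":
        df = pd.read_csv(path)
        if sex is not None and "sex" in df.columns:
            df = df[df["sex"] == sex]
        return cls(df["age_start"].to_numpy(), df["width"].to_numpy(),
                   df["m"].to_numpy(), sex)


@dataclass
class LEGainEstimate:
    """Years of (disease-free) life expectancy gained versus a reference."""

    label: str
    years_gained: float
    ci_low: float
    ci_high: float
    reference: str = "reference category (HR = 1)"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.years_gained + 1e-12
                and self.years_gained <= self.ci_high + 1e-12):
            raise LifeTableError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket point "
                f"estimate {self.years_gained}"
            )


def life_expectancy_from_rates(m, width, a: float = 0.5) -> np.ndarray | float:
    """Life expectancy at the first interval from a rate schedule.

    Vectorised over leading axes: ``m`` may have shape ``(..., k)`` with a
    shared ``width`` of shape ``(k,)`` whose last element is ``inf``.  This is
    the numerical core used by the Monte Carlo machinery, where thousands of
    sampled schedules are evaluated at once.
    """
    m = np.asarray(m, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(m[..., -1] <= 0):
        raise LifeTableError("open interval requires m > 0 (else expectancy diverges)")
    w = width[:-1]
    mc = m[..., :-1]
    q = w * mc / (1.0 + w * (1.0 - a) * mc)  # a = separation factor
    # survivors at interval starts (radix 1)
    surv = np.cumprod(1.0 - q, axis=-1)
    l = np.concatenate([np.ones(m.shape[:-1] + (1,)), surv], axis=-1)
    d = l[..., :-1] * q
    # L = w * (l_next + a*d) with l_next = l - d
    L_closed = w * ((l[..., :-1] - d) + a * d)
    L_open = l[..., -1] / m[..., -1]
    total = L_closed.sum(axis=-1) + L_open
    return total  # e at first interval, radix 1


def build_life_table(rates: BaselineRates, start_age: float | None = None,
                     a: float = 0.5) -> pd.DataFrame:
    """Full Chiang life table as a DataFrame.

    Columns: ``age_start, width, m, q, l, d, L, T, e``; radix 100,000.
    ``start_age`` (default: first boundary) truncates the schedule first.
    """
    if start_age is not None:
        rates = rates.from_age(start_age)
    m, w = rates.m, rates.width
    if m[-1] <= 0:
        raise LifeTableError("open interval requires m > 0 (else expectancy diverges)")
    k = m.size
    q = np.empty(k)
    q[:-1] = w[:-1] * m[:-1] / (1.0 + w[:-1] * (1.0 - a) * m[:-1])
    q[-1] = 1.0
    l = np.empty(k)
    l[0] = RADIX
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q
    L = np.empty(k)
    L[:-1] = w[:-1] * ((l[:-1] - d[:-1]) + a * d[:-1])
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return pd.DataFrame(
        {"age_start": rates.age_start, "width": w, "m": m, "q": q,
         "l": l, "d": d, "L": L, "T": T, "e": e}
    )


def adjust_rates(rates: BaselineRates, hr, calibration: str = "none",
                 prevalences=None, hrs_all=None) -> BaselineRates:
    """Multiply a rate schedule by a hazard ratio.

    calibration="none"
        ``m' = m * hr`` — the baseline schedule is read as the reference
        category's rates.
    calibration="population"
        ``m' = m * hr / sum_k(p_k * hr_k)`` — the baseline schedule is read as
        population-average rates; ``prevalences`` and ``hrs_all`` give the
        category mix, so the prevalence-weighted mean of adjusted rates
        reproduces ``m`` exactly.
    """
    hr = float(hr)
    if hr <= 0:
        raise LifeTableError("hazard ratio must be > 0")
    if calibration == "none":
        return rates.with_rates(rates.m * hr)
    if calibration == "population":
        if prevalences is None or hrs_all is None:
            raise LifeTableError("population calibration needs prevalences and hrs_all")
        p = np.asarray(prevalences, float)
        h = np.asarray(hrs_all, float)
        if not np.isclose(p.sum(), 1.0):
            raise LifeTableError("category prevalences must sum to 1")
        denom = float(np.sum(p * h))
        return rates.with_rates(rates.m * hr / denom)
    raise LifeTableError(f"unknown calibration mode {calibration!r}")


def _expectancy_at(rates: BaselineRates, start_age: float, hr: float,
                   calibration: str = "none", **cal_kw) -> float:
    adj = adjust_rates(rates, hr, calibration, **cal_kw)
    trunc = adj.from_age(start_age)
    return float(life_expectancy_from_rates(trunc.m, trunc.width))


def years_gained(hr_row, rates: BaselineRates, start_age: float,
                 calibration: str = "none", label: str | None = None,
                 **cal_kw) -> LEGainEstimate:
    """Life-expectancy gain of one HR row versus the HR = 1 reference.

    ``hr_row`` is anything with ``hr``, ``ci_low``, ``ci_high`` entries
    (a mapping or a pandas row).  Because expectancy is strictly decreasing in
    the hazard ratio, the gain CI comes from recomputing at the HR confidence
    limits: the upper HR limit gives the lower gain limit and vice versa.
    """
    hr = float(hr_row["hr"])
    lo = float(hr_row["ci_low"])
    hi = float(hr_row["ci_high"])
    if not (0 < lo <= hr <= hi):
        raise LifeTableError(f"invalid HR row (hr={hr}, ci=({lo}, {hi}))")
    e_ref = _expectancy_at(rates, start_age, 1.0, calibration, **cal_kw)
    point = _expectancy_at(rates, start_age, hr, calibration, **cal_kw) - e_ref
    lo_gain = _expectancy_at(rates, start_age, hi, calibration, **cal_kw) - e_ref
    hi_gain = _expectancy_at(rates, start_age, lo, calibration, **cal_kw) - e_ref
    if label is None:
        try:
            label = str(hr_row.get("label", ""))
        except AttributeError:
            label = ""
    return LEGainEstimate(label, point, lo_gain, hi_gain)


def sex_stratified_gains(hr_tables: dict, rates_by_sex: dict, start_age: float,
                         calibration: str = "none") -> pd.DataFrame:
    """Years gained per stratum, each computed on its own rate schedule.

    ``hr_tables`` maps stratum -> DataFrame with hr/ci_low/ci_high (+ label
    column optional); ``rates_by_sex`` maps stratum -> BaselineRates.
    """
    if set(hr_tables) != set(rates_by_sex):
        raise LifeTableError(
            f"strata mismatch: HRs for {sorted(hr_tables)}, rates for {sorted(rates_by_sex)}"
        )
    rows = []
    for stratum, table in hr_tables.items():
        rates = rates_by_sex[stratum]
        for _, r in table.iterrows():
            est = years_gained(r, rates, start_age, calibration,
                               label=str(r.get("label", "")))
            rows.append({"stratum": stratum, "label": est.label,
                         "years_gained": est.years_gained,
                         "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)
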