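"""Synthetic national-style baseline rate schedules.

The life-table machinery needs age-specific all-cause mortality rates and,
for the healthspan extension, age-specific incidence and prevalence of the
five chronic conditions.  Real national life tables and disease registers
are not bundled; these generators produce smooth, demographically plausible
stand-ins (Gompertz mortality, exponentially rising incidence, logistic
prevalence) in the same CSV dialect that user-supplied tables use, and are
labelled synthetic throughout.

Magnitudes are anchored loosely to a late-middle-aged UK-style cohort:
m(65) ~ 0.011/year, CVD the most common condition, dementia incidence rising
steepest with age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .healthspan import CONDITIONS, DiseaseRates
from .lifetable import BaselineRates

__all__ = ["synthetic_mortality_rates", "synthetic_disease_rates"]

_SEX_FACTOR = {None: 1.0, "male": 1.35, "female": 0.78}

# per-condition (incidence at 65 /person-year, log-slope per year of age,
#                prevalence at 65, prevalence log-odds slope per year)
_DISEASE_PARAMS = {
    "cvd":      (0.024, 0.055, 0.12, 0.055),
    "cancer":   (0.018, 0.045, 0.08, 0.045),
    "t2d":      (0.007, 0.020, 0.07, 0.030),
    "copd":     (0.0035, 0.050, 0.04, 0.050),
    "dementia": (0.0012, 0.120, 0.01, 0.110),
}


def _age_grid(age_min: float, age_max: float, width: float):
    starts = np.arange(age_min, age_max + 1e-9, width)
    widths = np.full(starts.size, float(width))
    widths[-1] = np.inf
    return starts, widths


def synthetic_mortality_rates(sex: str | None = None, age_min: float = 40.0,
                              age_max: float = 100.0,
                              width: float = 1.0) -> BaselineRates:
    """Gompertz all-cause mortality schedule m(x) = a*exp(b*x) (synthetic)."""
    starts, widths = _age_grid(age_min, age_max, width)
    b = 0.095
    a = 0.011 / np.exp(b * 65.0) * _SEX_FACTOR[sex]
    mid = starts + np.where(np.isinf(widths), 2.5, widths / 2.0)
    m = a * np.exp(b * mid)
    return BaselineRates(starts, widths, m, sex)


def synthetic_disease_rates(age_min: float = 40.0, age_max: float = 100.0,
                            width: float = 1.0,
                            relative_se: float = 0.08) -> DiseaseRates:
    """Synthetic incidence/prevalence schedules for the five conditions.

    Incidence rises exponentially with age; prevalence follows a logistic in
    age.  Standard errors are ``relative_se`` of the incidence and of the
    prevalence (floored so logit sampling stays well-behaved).
    """
    starts, widths = _age_grid(age_min, age_max, width)
    mid = starts + np.where(np.isinf(widths), 2.5, widths / 2.0)
    rows = []
    for cond in CONDITIONS:
        i65, slope, p65, pslope = _DISEASE_PARAMS[cond]
        inc = i65 * np.exp(slope * (mid - 65.0))
        logit65 = np.log(p65 / (1 - p65))
        prev = 1.0 / (1.0 + np.exp(-(logit65 + pslope * (mid - 65.0))))
        for a, i, p in zip(starts, inc, prev):
            rows.append({"age_start": a, "condition": cond,
                         "incidence": i, "incidence_se": relative_se * i,
                         "prevalence": p,
                         "prevalence_se": max(relative_se * p, 1e-4)})
    return DiseaseRates(pd.DataFrame(rows))
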