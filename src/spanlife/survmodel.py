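"""Proportional-hazards modelling of the joint SPAN exposures.

Two model families drive the life-table machinery:

* the 27-category joint tertile model — indicator terms for every
  sleep x MVPA x diet tertile combination (all-low as reference) plus the
  covariate set, fitted by Cox partial likelihood (Efron ties);
* restricted-cubic-spline dose-response models for a single continuous
  exposure (or the composite score), centred so the log hazard is 0 at a
  reference value (the 5th percentile by default).

Fitting is delegated to lifelines' CoxPHFitter; this module owns the design
construction (category dummies, the Harrell spline basis), the contrast /
delta-method arithmetic that turns coefficients into hazard-ratio tables,
and proportional-hazards diagnostics (Schoenfeld-residual time-trend tests,
martingale-residual linearity summaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prep import joint_triple

__all__ = [
    "CoxFit",
    "SplineFit",
    "rcs_basis",
    "fit_cox_joint",
    "fit_cox_rcs",
    "hazard_ratios",
    "ph_diagnostics",
]

Z975 = 1.959963984540054


class ModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# restricted cubic spline basis (Harrell convention)

def default_knots(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Knots at outer 5/95 percentiles with equally spaced inner quantiles.

    For the default 4 knots this is the 5/35/65/95 percentile placement.
    """
    if n_knots < 3:
        raise ModelError("restricted cubic splines need >= 3 knots")
    if n_knots == 4:
        q = [5, 35, 65, 95]
    else:
        q = np.linspace(5, 95, n_knots)
    return np.percentile(x, q)


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis, linear beyond the boundary knots.

    Returns an (n, k-1) array: the linear term plus k-2 truncated-cubic
    terms, each scaled by (t_k - t_1)^2 so coefficients share the scale of
    the linear term.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.sort(np.asarray(knots, dtype=float))
    k = t.size
    if k < 3:
        raise ModelError("restricted cubic splines need >= 3 knots")
    if np.unique(t).size != k:
        raise ModelError("knots must be distinct")
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (np.clip(x - t[j], 0, None) ** 3
                - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
                + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(term / norm)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fitted-model containers

@dataclass
class CoxFit:
    """Fitted joint-category Cox model.

    ``params``/``cov`` cover the category indicator block and covariates;
    the reference category carries an implicit coefficient of 0.
    """

    params: pd.Series
    cov: pd.DataFrame
    n_events: int
    category_col: str
    reference_category: int
    category_counts: pd.DataFrame     # index, n, events
    zero_event_categories: list[int]
    fitter: object = field(repr=False, default=None)
    model_df: pd.DataFrame = field(repr=False, default=None)

    def term(self, category: int) -> str:
        return f"{self.category_col}_{category}"


@dataclass
class SplineFit:
    """Centred restricted-cubic-spline Cox dose-response fit."""

    exposure: str
    knots: np.ndarray
    beta: np.ndarray                  # spline-term coefficients
    cov: np.ndarray                   # their covariance block
    reference_value: float
    support: tuple[float, float]      # fitted (winsorised) exposure range
    n_events: int
    fitter: object = field(repr=False, default=None)

    def log_hr(self, x) -> tuple[np.ndarray, np.ndarray]:
        """(log HR, SE) at x relative to the reference value."""
        b = rcs_basis(x, self.knots) - rcs_basis([self.reference_value], self.knots)
        est = b @ self.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", b, self.cov, b))
        return est, se

    def hazard_ratios(self, grid) -> pd.DataFrame:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        est, se = self.log_hr(grid)
        return pd.DataFrame({
            "x": grid, "hr": np.exp(est),
            "ci_low": np.exp(est - Z975 * se),
            "ci_high": np.exp(est + Z975 * se),
        })

    def argmin_hr(self, n_grid: int = 2001, within_knots: bool = True) -> float:
        """Exposure value minimising the fitted hazard (curve nadir).

        By default the search is restricted to the span of the knots: beyond
        the boundary knots the restricted spline is linear extrapolation, so
        an extremum there is an artefact of the tail slope, not a nadir.
        """
        lo, hi = (self.knots[0], self.knots[-1]) if within_knots else self.support
        g = np.linspace(lo, hi, n_grid)
        est, _ = self.log_hr(g)
        return float(g[np.argmin(est)])


# ---------------------------------------------------------------------------
# fitting

def _fit_cph(model_df: pd.DataFrame, duration_col: str, event_col: str):
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model_df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ModelError(f"Cox model failed to converge: {err}") from err
    return cph


def fit_cox_joint(cohort: pd.DataFrame, duration_col: str, event_col: str,
                  category_col: str = "joint_category",
                  covariates: list[str] | None = None,
                  reference: int = 1) -> CoxFit:
    """Fit the joint-category Cox model (Efron ties, lifelines backend).

    Categories with zero events are excluded from the risk sets (their rows
    are dropped) and recorded on the fit; their hazard ratios are reported as
    missing rather than diverging estimates.
    """
    covariates = list(covariates or [])
    df = cohort.dropna(subset=[category_col]).copy()
    df[category_col] = df[category_col].astype(int)
    counts = (df.groupby(category_col)
                .agg(n=(event_col, "size"), events=(event_col, "sum"))
                .reset_index()
                .rename(columns={category_col: "category_index"}))
    zero = counts.loc[counts["events"] == 0, "category_index"].tolist()
    if reference in zero:
        raise ModelError(f"reference category {reference} has zero events")
    if zero:
        warnings.warn(f"categories with zero events excluded from fit: {zero}")
        df = df[~df[category_col].isin(zero)]

    dummies = pd.get_dummies(df[category_col], prefix=category_col, dtype=float)
    ref_col = f"{category_col}_{reference}"
    if ref_col not in dummies.columns:
        raise ModelError(f"reference category {reference} absent from data")
    dummies = dummies.drop(columns=ref_col)
    model_df = pd.concat(
        [df[[duration_col, event_col] + covariates].reset_index(drop=True),
         dummies.reset_index(drop=True)], axis=1)
    cph = _fit_cph(model_df, duration_col, event_col)
    return CoxFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        n_events=int(df[event_col].sum()),
        category_col=category_col,
        reference_category=reference,
        category_counts=counts,
        zero_event_categories=zero,
        fitter=cph,
        model_df=model_df,
    )


def hazard_ratios(fit: CoxFit, categories=None) -> pd.DataFrame:
    """HR table for the joint categories (reference row exactly 1).

    Columns: category_index, sleep_t, mvpa_t, diet_t, hr, ci_low, ci_high,
    n, events.  Zero-event categories appear with missing HRs.
    """
    counts = fit.category_counts.set_index("category_index")
    if categories is None:
        categories = counts.index.tolist()
    rows = []
    for cat in categories:
        cat = int(cat)
        if cat not in counts.index:
            raise ModelError(f"category {cat} absent from the fitted data")
        s_t, m_t, d_t = joint_triple(cat)
        row = {"category_index": cat, "sleep_t": s_t, "mvpa_t": m_t,
               "diet_t": d_t, "n": int(counts.loc[cat, "n"]),
               "events": int(counts.loc[cat, "events"])}
        if cat == fit.reference_category:
            row.update(hr=1.0, ci_low=1.0, ci_high=1.0)
        elif cat in fit.zero_event_categories:
            row.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan)
        else:
            term = fit.term(cat)
            beta = float(fit.params[term])
            se = float(np.sqrt(fit.cov.loc[term, term]))
            row.update(hr=np.exp(beta), ci_low=np.exp(beta - Z975 * se),
                       ci_high=np.exp(beta + Z975 * se))
        rows.append(row)
    return pd.DataFrame(rows)


def fit_cox_rcs(cohort: pd.DataFrame, duration_col: str, event_col: str,
                exposure: str, covariates: list[str] | None = None,
                n_knots: int = 4, knots=None,
                reference_pct: float = 5.0) -> SplineFit:
    """Restricted-cubic-spline Cox dose-response for one continuous exposure.

    The curve is centred at the ``reference_pct`` percentile of the exposure
    (log HR = 0 there by construction).
    """
    covariates = list(covariates or [])
    x = cohort[exposure].to_numpy(float)
    if np.unique(x).size < max(n_knots, 3):
        raise ModelError(f"{exposure}: fewer distinct values than knots")
    knots = default_knots(x, n_knots) if knots is None else np.asarray(knots, float)
    basis = rcs_basis(x, knots)
    cols = [f"rcs_{exposure}_{j}" for j in range(basis.shape[1])]
    model_df = pd.concat(
        [cohort[[duration_col, event_col] + covariates].reset_index(drop=True),
         pd.DataFrame(basis, columns=cols)], axis=1)
    cph = _fit_cph(model_df, duration_col, event_col)
    beta = cph.params_[cols].to_numpy()
    cov = cph.variance_matrix_.loc[cols, cols].to_numpy()
    return SplineFit(
        exposure=exposure,
        knots=np.sort(knots),
        beta=beta,
        cov=cov,
        reference_value=float(np.percentile(x, reference_pct)),
        support=(float(x.min()), float(x.max())),
        n_events=int(cohort[event_col].sum()),
        fitter=cph,
    )


def contrast_hr(coef: float, se: float) -> tuple[float, float, float]:
    """exp(coef) with the delta-method 95% CI (hr, lo, hi)."""
    return (float(np.exp(coef)), float(np.exp(coef - Z975 * se)),
            float(np.exp(coef + Z975 * se)))


# ---------------------------------------------------------------------------
# diagnostics

def ph_diagnostics(fit: CoxFit, alpha: float = 0.05,
                   continuous_covariates: list[str] | None = None) -> dict:
    """Proportional-hazards and functional-form diagnostics.

    Per-term Schoenfeld-residual time-trend tests (rank-transformed time) and
    a global test (Sidak combination of the per-term p-values — conservative
    under correlated terms); martingale-residual Pearson correlations against
    each continuous covariate.  Violations flagged at ``alpha``.
    """
    from lifelines.statistics import proportional_hazard_test

    if fit.fitter is None or fit.model_df is None:
        raise ModelError("fit does not retain its fitter; cannot run diagnostics")
    res = proportional_hazard_test(fit.fitter, fit.model_df, time_transform="rank")
    per_term = res.summary["p"]
    if isinstance(per_term.index, pd.MultiIndex):
        per_term = per_term.droplevel(-1)
    per_term = per_term.groupby(level=0).min()
    k = len(per_term)
    p_min = float(per_term.min())
    p_global = float(1.0 - (1.0 - p_min) ** k)

    mart = None
    mart_rows = []
    if continuous_covariates:
        mart = fit.fitter.compute_residuals(fit.model_df, "martingale")
        for cov in continuous_covariates:
            r, p = stats.pearsonr(fit.model_df[cov], mart["martingale"])
            mart_rows.append({"covariate": cov, "pearson_r": float(r),
                              "p": float(p), "flag": bool(p < alpha)})
    return {
        "schoenfeld_p": {t: float(p) for t, p in per_term.items()},
        "global_p": p_global,
        "global_violation": p_global < alpha,
        "flagged_terms": [t for t, p in per_term.items() if p < alpha],
        "martingale": mart_rows,
        "alpha": alpha,
    }
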