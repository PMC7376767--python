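"""Cohort-level statistics: CIT, paired t tests, and FF–SUV regressions.

The analyses mirror a two-cohort observational design: within-subject
comparison of fat fraction between PET-positive and PET-negative depot
regions (paired t test), per-cohort simple linear regression of mean SUV on
depot fat fraction, a pooled regression after within-cohort z-scaling (the
two cohorts used different Dixon sequences, hence different FF scales), and
a multiple regression adding age, BMI, and cold-induced thermogenesis (CIT)
as predictors. All p-values are two-sided; no multiplicity correction is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SubjectRecord",
    "RegressionResult",
    "cit_percent",
    "paired_t",
    "zscale",
    "simple_linreg",
    "pooled_z_regression",
    "multiple_linreg",
    "records_to_frame",
]


@dataclass
class SubjectRecord:
    """One study participant's demographics, calorimetry, and imaging summary."""

    id: str
    cohort: int
    age: float
    bmi: float
    weight: float
    ee_warm: float | None = None
    ee_cold: float | None = None
    cit: float | None = None
    ff_sc_total: float | None = None
    ff_active: float | None = None
    ff_sphere_pos: float | None = None
    ff_sphere_neg: float | None = None
    suv_mean: float | None = None
    bat_positive: bool = True

    def __post_init__(self) -> None:
        if self.age <= 0 or self.bmi <= 0 or self.weight <= 0:
            raise ValueError("age, BMI, and weight must be positive")
        for name in ("ff_sc_total", "ff_active", "ff_sphere_pos", "ff_sphere_neg"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1000):
                raise ValueError(f"{name} must lie in [0, 1000] per mille")
        if self.cit is None and self.ee_warm and self.ee_cold:
            self.cit = cit_percent(self.ee_warm, self.ee_cold)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary: per-predictor estimates and model-level fit."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adjusted_r_squared: float
    n: int
    residual_df: int

    def table(self) -> pd.DataFrame:
        """Coefficient table with Estimate / Std. error / t value / p columns."""
        return pd.DataFrame({
            "Estimate": self.coefficients,
            "Std. error": self.std_errors,
            "t value": self.t_values,
            "p": self.p_values,
        })


def cit_percent(ee_warm: float, ee_cold: float) -> float:
    """Cold-induced thermogenesis: percent rise of resting EE under cold.

    100 * (EE_cold - EE_warm) / EE_warm; negative if cold lowers expenditure.
    """
    if ee_warm <= 0:
        raise ValueError("warm resting energy expenditure must be positive")
    return 100.0 * (ee_cold - ee_warm) / ee_warm


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if np.isclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), n - 1, float(res.pvalue)


def zscale(values) -> np.ndarray:
    """Standardise to mean 0 and sample (ddof=1) SD 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to z-scale")
    sd = v.std(ddof=1)
    if np.isclose(sd, 0.0):
        raise ValueError("zero standard deviation: cannot z-scale")
    return (v - v.mean()) / sd


def _from_sm(fit, names) -> RegressionResult:
    params = dict(zip(names, (float(v) for v in fit.params)))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2, adj = float(fit.rsquared), float(fit.rsquared_adj)
    if not np.isfinite(r2):  # constant response: nothing to explain
        r2, adj = 0.0, 0.0
    return RegressionResult(
        coefficients=params,
        std_errors=dict(zip(names, (float(v) for v in fit.bse))),
        t_values=dict(zip(names, (float(v) for v in fit.tvalues))),
        p_values=dict(zip(names, (float(v) for v in fit.pvalues))),
        r_squared=r2,
        adjusted_r_squared=adj,
        n=int(fit.nobs),
        residual_df=int(fit.df_resid),
    )


def simple_linreg(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with an intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.isclose(x.std(), 0.0):
        raise ValueError("constant predictor: slope is undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return _from_sm(fit, ["intercept", "slope"])


def multiple_linreg(y, predictors: pd.DataFrame,
                    standardize: bool = True) -> RegressionResult:
    """OLS of y on named predictor columns, z-scaled by default.

    With ``standardize`` both the response and every predictor are z-scaled
    (sample SD), so estimates are dimensionless standardized coefficients.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("response and predictors differ in length")
    if n < p + 2:
        raise ValueError("too few observations for the number of predictors")
    if standardize:
        y = zscale(y)
        X = X.apply(zscale, axis=0)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.values]))
    if rank < p + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design: columns {worst[0]!r} and "
                         f"{worst[1]!r} are collinear")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return _from_sm(fit, ["intercept", *X.columns])


def records_to_frame(records) -> pd.DataFrame:
    """Subject records as a DataFrame (one row per participant)."""
    return pd.DataFrame([vars(r) for r in records])


def pooled_z_regression(records, x_field: str = "ff_sc_total",
                        y_field: str = "suv_mean",
                        scope: str = "per_cohort",
                        include_bat_negative: bool = False) -> RegressionResult:
    """Simple regression on z-scaled values pooled across cohorts.

    With ``scope='per_cohort'`` (default) x and y are standardized within
    each cohort before pooling, removing between-sequence scale differences;
    ``scope='pooled'`` standardizes across all subjects at once. BAT-negative
    subjects are excluded unless requested otherwise.
    """
    if scope not in ("per_cohort", "pooled"):
        raise ValueError("scope must be 'per_cohort' or 'pooled'")
    df = records_to_frame(records)
    if not include_bat_negative:
        df = df[df["bat_positive"]]
    df = df.dropna(subset=[x_field, y_field])
    if scope == "per_cohort":
        parts = []
        for _, grp in df.groupby("cohort"):
            if len(grp) < 3:
                raise ValueError("need at least 3 subjects per cohort")
            parts.append(pd.DataFrame({
                "x": zscale(grp[x_field]),
                "y": zscale(grp[y_field]),
            }))
        z = pd.concat(parts, ignore_index=True)
    else:
        z = pd.DataFrame({"x": zscale(df[x_field]), "y": zscale(df[y_field])})
    return simple_linreg(z["x"], z["y"])
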