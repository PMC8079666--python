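"""Group-level inference: disease burden, group x age regression, correlations.

The clinical questions: does the myelin water signal fraction (f_m) or the
myelin–axonal frequency split (delta omega) differ between premanifest
Huntington's-disease gene carriers and controls once age is accounted for;
and does f_m track executive function or proximity to onset (disease burden
score, DBS = age * (CAG - 35.5))?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "disease_burden_score",
    "fit_group_age_model",
    "spearman_rho",
    "partial_correlation",
    "bonferroni_adjust",
]


def disease_burden_score(age: float, cag: float) -> float:
    """DBS = age * (CAG - 35.5), a proxy for proximity to clinical onset."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive")
    out = age * (np.asarray(cag, dtype=float) - 35.5)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RegressionResult:
    """OLS coefficients (estimate, SE, p) for intercept/group/age/interaction."""

    coefficients: dict
    r_squared: float
    n: int
    f_statistic: float
    f_pvalue: float

    def coef(self, term: str) -> float:
        return self.coefficients[term]["estimate"]

    def pvalue(self, term: str) -> float:
        return self.coefficients[term]["p_value"]


def fit_group_age_model(
    table: pd.DataFrame, outcome: str, center_age: bool = False
) -> RegressionResult:
    """OLS of an outcome on group (0 = control, 1 = HD), age and group x age.

    ``center_age=True`` subtracts the sample mean age first, which makes the
    group coefficient the group difference at the mean age rather than the
    extrapolated difference at age zero (the interaction term is unaffected).
    """
    needed = {"group", "age", outcome}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    df = table.dropna(subset=list(needed)).copy()
    group = (
        df["group"].map({"control": 0, "HD": 1, 0: 0, 1: 1}).astype(float).to_numpy()
    )
    if np.any(np.isnan(group)):
        raise ValueError("group must be 'HD'/'control' or 0/1")
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be present")
    for g in (0, 1):
        if (group == g).sum() < 5:
            raise ValueError("need >= 5 rows per group")
    age = df["age"].to_numpy(dtype=float)
    if center_age:
        age = age - age.mean()
    y = df[outcome].to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(age), group, age, group * age])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, design).fit()
    terms = ("intercept", "group", "age", "group_age")
    coefficients = {
        term: {
            "estimate": float(fit.params[i]),
            "se": float(fit.bse[i]),
            "p_value": float(fit.pvalues[i]),
        }
        for i, term in enumerate(terms)
    }
    return RegressionResult(
        coefficients=coefficients,
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def partial_correlation(x, y, covariate) -> tuple[float, float]:
    """Rank-based partial correlation of x and y controlling for a covariate.

    Ranks of x and y are each residualized on the rank of the covariate by
    OLS and the residuals are correlated with Spearman's rho (a rank
    analogue of partial correlation).  A constant covariate falls back to
    the plain Spearman correlation with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.size == y.size == z.size) or x.size < 5:
        raise ValueError("need >= 5 triples")
    if np.ptp(z) == 0:
        warnings.warn(
            "constant covariate; falling back to plain Spearman correlation",
            stacklevel=2,
        )
        return spearman_rho(x, y)
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    design = np.column_stack([np.ones_like(rz), rz])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.allclose(res_x, 0) or np.allclose(res_y, 0):
        # nothing left once the covariate is removed
        return 0.0, 1.0
    rho, p = sps.spearmanr(res_x, res_y)
    return float(rho), float(p)


def bonferroni_adjust(
    p_values, family_alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted p-values and reject decisions at the family alpha."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.minimum(1.0, p * p.size)
    return adjusted, adjusted < family_alpha
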