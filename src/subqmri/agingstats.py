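"""Correlation statistics for cross-sectional aging analyses.

Every aging claim reduces to a Pearson (or partial) correlation of an
outcome against continuous age, tested two-sided at alpha = 0.05 and
Bonferroni-corrected within a declared family of tests. Partial
correlations control nuisance variables (inter-rater Dice, total ventricle
volume) by residualizing both the outcome and age on the covariates, with
df = n - 2 - k for k covariates. Pairs of correlations (e.g. the same
analysis run with two different rater pairs) are compared with the
two-sample Fisher r-to-z test.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "FisherComparison",
    "pearson_age_correlation",
    "bonferroni",
    "fisher_compare",
    "regression_ci",
]


@dataclass
class CorrelationResult:
    """One (partial) correlation test against age."""

    outcome: str
    covariates: tuple[str, ...]
    r: float
    df: int
    t: float
    p_raw: float
    p_corrected: float | None = None
    family: str | None = None
    family_size: int | None = None

    @property
    def significant(self) -> bool:
        """Corrected p < 0.05 (raw p if no correction has been applied)."""
        p = self.p_corrected if self.p_corrected is not None else self.p_raw
        return p < 0.05


@dataclass
class FisherComparison:
    """Two-sample comparison of independent correlation coefficients."""

    r1: float
    n1: int
    r2: float
    n2: int
    z: float = dc_field(init=False)
    p: float = dc_field(init=False)

    def __post_init__(self) -> None:
        for r, n in ((self.r1, self.n1), (self.r2, self.n2)):
            if abs(r) >= 1.0:
                raise ValueError("Fisher comparison requires |r| < 1")
            if n <= 3:
                raise ValueError("Fisher comparison requires n > 3")
        se = np.sqrt(1.0 / (self.n1 - 3) + 1.0 / (self.n2 - 3))
        self.z = float((np.arctanh(self.r1) - np.arctanh(self.r2)) / se)
        self.p = float(2.0 * stats.norm.sf(abs(self.z)))


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of y regressed on [1, x] (ordinary least squares)."""
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def pearson_age_correlation(
    values,
    ages,
    covariates: dict | None = None,
    outcome: str = "",
) -> CorrelationResult:
    """Pearson correlation of an outcome with age, optionally partial.

    With covariates, both the outcome and age are residualized on the
    covariate block (double residualization, equivalent to the
    precision-matrix partial correlation), and df = n - 2 - k.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ValueError("values and ages must be 1-D and the same length")
    if np.any(np.isnan(y)) or np.any(np.isnan(a)):
        raise ValueError("missing values are not supported")
    cov_names: tuple[str, ...] = ()
    k = 0
    if covariates:
        cov_names = tuple(covariates.keys())
        cmat = np.column_stack([np.asarray(covariates[c], float) for c in cov_names])
        if cmat.shape[0] != len(y):
            raise ValueError("covariates must have the same length as values")
        k = cmat.shape[1]
    n = len(y)
    if n < 4 + k:
        raise ValueError(f"need at least {4 + k} observations, got {n}")
    if np.std(y) == 0 or np.std(a) == 0:
        raise ValueError("zero variance in values or ages")
    if k:
        y = _residualize(y, cmat)
        a = _residualize(a, cmat)
        if np.std(y) == 0 or np.std(a) == 0:
            raise ValueError("covariates absorb all variance")
    r = float(np.corrcoef(y, a)[0, 1])
    df = n - 2 - k
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        outcome=outcome,
        covariates=cov_names,
        r=r,
        df=df,
        t=float(t),
        p_raw=p,
    )


def bonferroni(
    results: list[CorrelationResult],
    family: str,
    family_size: int | None = None,
) -> list[CorrelationResult]:
    """Bonferroni-correct a family of tests: p_corr = min(1, m * p_raw).

    The family size m defaults to the number of results passed (it is a
    property of the declared family, never a constant).
    """
    if not results:
        raise ValueError("empty test family")
    m = family_size if family_size is not None else len(results)
    for res in results:
        res.p_corrected = min(1.0, m * res.p_raw)
        res.family = family
        res.family_size = m
    return results


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> FisherComparison:
    """Fisher r-to-z comparison of two independent correlations.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p value.
    """
    return FisherComparison(r1=r1, n1=n1, r2=r2, n2=n2)


def regression_ci(
    values,
    ages,
    at_ages=None,
    level: float = 0.95,
):
    """OLS fit of value on age with the pointwise CI of the conditional mean.

    Returns (intercept, slope, grid_ages, fitted, lower, upper). The band
    uses the t distribution with n - 2 df and the hat-matrix leverage, so
    it is narrowest at the mean age and collapses as residual variance
    vanishes.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(y) != len(a) or y.ndim != 1:
        raise ValueError("values and ages must be 1-D and the same length")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(a) == 0:
        raise ValueError("degenerate ages: no variance")
    design = np.column_stack([np.ones(n), a])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df = n - 2
    s2 = float(resid @ resid) / df
    sxx = float(((a - a.mean()) ** 2).sum())
    grid = np.linspace(a.min(), a.max(), 100) if at_ages is None else np.asarray(
        at_ages, dtype=float
    )
    fitted = coef[0] + coef[1] * grid
    se_mean = np.sqrt(s2 * (1.0 / n + (grid - a.mean()) ** 2 / sxx))
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)
    return (
        float(coef[0]),
        float(coef[1]),
        grid,
        fitted,
        fitted - tcrit * se_mean,
        fitted + tcrit * se_mean,
    )
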