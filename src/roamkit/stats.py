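"""Shared inferential primitives: simple OLS, Pearson correlation, CV.

Trend statistics throughout the pipeline (RE decline, variance trajectories,
repeatability trend) reduce to simple regression of one response on one
predictor, reported the way behavioural papers print them: slope, F with
(1, n-2) degrees of freedom, adjusted R² and the two-sided p.  Fitting is
delegated to ``statsmodels``; correlation to ``scipy``.  No multiple-testing
correction is applied anywhere — pairwise correlation reports carry raw
p-values with a cautionary flag instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = ["OlsFit", "CorrelationResult", "ols", "pearson", "cv", "correlation_matrix"]


@dataclass(frozen=True)
class OlsFit:
    slope: float
    intercept: float
    F: float
    df: tuple[int, int]
    r2: float
    adj_r2: float
    p: float

    def __str__(self) -> str:  # printed like the field reports trends
        return (
            f"slope={self.slope:.4g}, F({self.df[0]}|{self.df[1]})={self.F:.2f}, "
            f"p={self.p:.3g}, adj. R2={self.adj_r2:.2f}"
        )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float


def ols(x, y) -> OlsFit:
    """Least-squares fit of ``y`` on ``x`` with F-test and adjusted R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("OLS trend needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    tiny = 1e-12 * max(1.0, float(np.sum(y**2)))
    if float(fit.centered_tss) <= tiny:
        # Constant response: no variance to explain.
        F, p, r2, adj_r2 = 0.0, 1.0, 0.0, 0.0
    elif fit.ssr <= tiny:
        # Numerically perfect fit: statsmodels' F is a 0/0.
        F, p, r2, adj_r2 = np.inf, 0.0, 1.0, 1.0
    else:
        F = float(fit.fvalue)
        p = float(fit.f_pvalue)
        r2 = float(fit.rsquared)
        adj_r2 = float(fit.rsquared_adj)
    return OlsFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        F=F,
        df=(1, n - 2),
        r2=r2,
        adj_r2=adj_r2,
        p=p,
    )


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with the two-sided Student-t test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input; correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return CorrelationResult(r=r, t=float(t), df=n - 2, p=float(p))


def cv(values=None, *, mean: float | None = None, sd: float | None = None) -> float:
    """Coefficient of variation, ``100 * sd / mean``, in percent.

    Either a sample (sd computed with the n-1 denominator) or a printed
    ``(mean, sd)`` pair may be supplied.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError("cv from data needs at least 2 values")
        mean = float(np.mean(v))
        sd = float(np.std(v, ddof=1))
    if mean is None or sd is None:
        raise ValueError("provide values or both mean and sd")
    if mean <= 0:
        raise ValueError("cv undefined for mean <= 0")
    return 100.0 * sd / mean


def correlation_matrix(wide: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Pearson correlations of the columns of a wide table.

    One row per animal, one column per variable (e.g. cRE at chosen dates,
    weight, behaviour frequencies, RMR).  Returns a long table
    ``var_a,var_b,r,t,df,p,flag`` where ``flag`` marks raw ``p < alpha`` —
    with the explicit caveat that no alpha correction is applied.
    """
    cols = [c for c in wide.columns if pd.api.types.is_numeric_dtype(wide[c])]
    rows = []
    for a, b in combinations(cols, 2):
        sub = wide[[a, b]].dropna()
        try:
            res = pearson(sub[a].to_numpy(), sub[b].to_numpy())
        except ValueError:
            continue
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r": res.r,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "flag": "*uncorrected*" if res.p < alpha else "",
            }
        )
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "t", "df", "p", "flag"])
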