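"""Quadratic and cubic QSPR regression of properties on a topological index.

Each physicochemical property y is regressed on one index x by ordinary
least squares on the monomial design (1, x, x^2[, x^3]).  Reported fit
statistics follow the usual OLS conventions:

    R^2 = 1 - RSS/TSS                    R = +sqrt(R^2)
    SE  = sqrt(RSS / (n - p - 1))        (residual standard error, p slopes)
    F   = (R^2/p) / ((1 - R^2)/(n - p - 1)),  p-value from F(p, n - p - 1)

The fits themselves go through statsmodels; the degenerate constant-response
case (TSS = 0) is defined as R^2 = 0, F = 0, p = 1 rather than 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RankDeficiencyError", "QSPRFit", "fit_polynomial", "model_table"]


class RankDeficiencyError(ValueError):
    """Design matrix is rank-deficient (e.g. too few distinct x values)."""


@dataclass(frozen=True)
class QSPRFit:
    """One polynomial OLS fit: y = a + b x + c x^2 [+ d x^3]."""

    degree: int
    coefficients: tuple[float, ...]  # (a, b, c[, d]), intercept first
    n: int
    R: float
    R2: float
    SE: float
    F: float
    p: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c * x**k for k, c in enumerate(self.coefficients))

    def equation(self, decimals: int = 4) -> str:
        terms = [f"{self.coefficients[0]:.{decimals}f}"]
        for k, c in enumerate(self.coefficients[1:], start=1):
            op = "+" if c >= 0 else "-"
            power = "x" if k == 1 else f"x^{k}"
            terms.append(f"{op}{abs(c):.{decimals}f}{power}")
        return "y=" + "".join(terms)


def fit_polynomial(x, y, degree: int) -> QSPRFit:
    """OLS fit of y on (1, x, ..., x^degree) with the fit statistics above."""
    if degree not in (2, 3):
        raise ValueError(f"degree must be 2 or 3, got {degree}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d vectors")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")

    # a polynomial design on (1, x, ..., x^d) is singular iff fewer than d+1
    # distinct x values; matrix_rank is unreliable here because raw index
    # scales (x^3 ~ 1e9) make the design ill-conditioned but still full rank
    if len(np.unique(x)) < degree + 1:
        raise RankDeficiencyError(
            f"design matrix rank-deficient: {len(np.unique(x))} distinct x "
            f"values for degree {degree}"
        )
    X = np.vander(x, degree + 1, increasing=True)

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        # constant response: the model explains nothing and nothing needs
        # explaining; define R^2 = 0, F = 0, p = 1
        beta = np.zeros(degree + 1)
        beta[0] = y[0] if n else 0.0
        return QSPRFit(degree, tuple(beta), n, 0.0, 0.0, 0.0, 0.0, 1.0)

    res = sm.OLS(y, X).fit()
    r2 = float(res.rsquared)
    se = float(np.sqrt(res.ssr / (n - degree - 1)))
    f_stat = float(res.fvalue)
    p_val = float(res.f_pvalue)
    return QSPRFit(
        degree=degree,
        coefficients=tuple(float(b) for b in res.params),
        n=n,
        R=float(np.sqrt(max(r2, 0.0))),
        R2=r2,
        SE=se,
        F=f_stat,
        p=p_val,
    )


def model_table(
    properties: pd.DataFrame,
    index_values,
    index_name: str,
    *,
    degrees: tuple[int, ...] = (2, 3),
) -> pd.DataFrame:
    """Fit every property on one index at each degree; mirror the report layout.

    ``properties`` is the drugs x properties matrix; ``index_values`` the
    aligned per-drug index column.  Returns one row per (property, degree)
    with the model equation and statistics.
    """
    x = np.asarray(index_values, dtype=float)
    if x.size != len(properties):
        raise ValueError("index_values not aligned with property table rows")
    rows = []
    for prop in properties.columns:
        y = properties[prop].to_numpy(dtype=float)
        for degree in degrees:
            fit = fit_polynomial(x, y, degree)
            rows.append(
                {
                    "index": index_name,
                    "property": prop,
                    "model": {2: "Quadratic", 3: "Cubic"}[degree],
                    "equation": fit.equation(),
                    "R": fit.R,
                    "R2": fit.R2,
                    "SE": fit.SE,
                    "F": fit.F,
                    "p": fit.p,
                }
            )
    return pd.DataFrame(rows)


def round_for_report(table: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Rounded copy for export; p-values floor-display as 0.000 at 3 dp."""
    out = table.copy()
    for col in ("R", "R2", "SE", "F", "p"):
        if col in out:
            out[col] = out[col].round(decimals)
    return out
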