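"""Temporal trends: nonlinear period fits on a 5-knot regression-spline
basis, per-species standardized abundance slopes with significance
classes, and abundance-vs-change diagnostics.

Species slopes follow the standardize-then-regress recipe: yearly totals
are scaled to mean 0 / SD 1, regressed on calendar year by OLS, and the
slope is multiplied by the study span (5 years) to give a predicted
change in SD units over the study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendFit",
    "SpeciesTrend",
    "fit_spline_trend",
    "species_trend",
    "classify_trends",
    "abundance_change_correlation",
]


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis with K knots -> K columns including the
    intercept (linear beyond the boundary knots). Standard truncated-power
    construction: 1, x, and d_j(x) - d_{K-2}(x) for j = 0..K-3 with
    d_j(x) = ((x - k_j)_+^3 - (x - k_{K-1})_+^3) / (k_{K-1} - k_j)."""
    K = len(knots)
    cols = [np.ones_like(x), x]
    if K >= 3:
        def d(j):
            num = (np.clip(x - knots[j], 0, None) ** 3
                   - np.clip(x - knots[K - 1], 0, None) ** 3)
            return num / (knots[K - 1] - knots[j])

        dK2 = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - dK2)
    return np.column_stack(cols)


@dataclass
class TrendFit:
    """Least-squares regression-spline fit of a metric on a period axis."""

    knots: np.ndarray
    coefficients: np.ndarray
    fitted: np.ndarray
    adjusted_r2: float
    p_value: float
    r2: float
    df_model: int
    reduced_basis: bool = False

    def predict(self, x_new) -> np.ndarray:
        b = _natural_spline_basis(np.asarray(x_new, float), self.knots)
        return b @ self.coefficients


def fit_spline_trend(x, y, k: int = 5) -> TrendFit:
    """Fit y on a natural cubic regression-spline basis in x with ``k``
    knots at quantiles of the distinct x values.

    When x has fewer than ``k`` distinct values the knots collapse onto
    the distinct values (flagged ``reduced_basis``) and the fit is the
    saturated means model. Reports adjusted R² and the overall F-test
    p-value of the regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    ux = np.unique(x)
    reduced = len(ux) < k
    if len(ux) < 2:
        raise ValueError("need at least 2 distinct x values")
    if reduced:
        knots = ux
    else:
        knots = np.quantile(ux, np.linspace(0, 1, k))
        knots = np.unique(knots)
    basis = _natural_spline_basis(x, knots)
    n, p = basis.shape
    if n <= p:
        raise ValueError(f"n = {n} observations <= {p} parameters")

    coef, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)
    fitted = basis @ coef
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    df_model = p - 1
    df_resid = n - p
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    if ss_res <= 1e-12 * max(ss_tot, 1.0):
        p_value = 0.0
    else:
        f = (r2 / df_model) / ((1.0 - r2) / df_resid)
        p_value = float(stats.f.sf(f, df_model, df_resid))
    return TrendFit(
        knots=knots, coefficients=coef, fitted=fitted,
        adjusted_r2=float(adj_r2), p_value=p_value, r2=float(r2),
        df_model=df_model, reduced_basis=reduced,
    )


#: p-value cutoffs: (stable above, weak above, strong at or below)
DEFAULT_CUTOFFS = (0.1, 0.05, 0.01)


@dataclass
class SpeciesTrend:
    """Standardized abundance trend of one species."""

    species: str
    slope_sd_per_year: float
    change_5yr: float
    p_value: float
    trend_class: str
    strong: bool
    total_abundance: float
    yearly_cv: float
    degenerate: bool = False


def _classify(slope: float, p: float,
              cutoffs=DEFAULT_CUTOFFS) -> tuple[str, bool]:
    stable_above, weak_above, strong_at = cutoffs
    if not np.isfinite(p) or p > stable_above:
        return "stable", False
    direction = "decline" if slope < 0 else "increase"
    if p > weak_above:
        return f"weak {direction}", False
    return direction, p <= strong_at


def species_trend(
    counts_by_year,
    years,
    species: str = "",
    cutoffs=DEFAULT_CUTOFFS,
) -> SpeciesTrend:
    """Standardized abundance slope for one species.

    Yearly totals are standardized to mean 0 / sample SD 1 and regressed
    on calendar year; ``change_5yr`` is slope x 5 (SD units over the
    study span); two-sided p from the slope t-test. Constant series get
    slope 0, missing p, class "stable", and a degenerate flag.
    """
    y = np.asarray(counts_by_year, dtype=float)
    x = np.asarray(years, dtype=float)
    if y.shape != x.shape or len(y) < 3:
        raise ValueError("need >= 3 paired (year, count) values")
    total = float(y.sum())
    cv = float("nan")
    if y.mean() > 0:
        cv = 100.0 * y.std(ddof=1) / y.mean()
    sd = y.std(ddof=1)
    if sd == 0:
        return SpeciesTrend(species, 0.0, 0.0, float("nan"), "stable",
                            False, total, cv, degenerate=True)
    z = (y - y.mean()) / sd
    res = stats.linregress(x, z)
    slope = float(res.slope)
    p = float(res.pvalue)
    cls, strong = _classify(slope, p, cutoffs)
    return SpeciesTrend(species, slope, 5.0 * slope, p, cls, strong,
                        total, cv)


def classify_trends(trends: list[SpeciesTrend]) -> pd.DataFrame:
    """Counts and proportions of species per trend class."""
    if not trends:
        raise ValueError("no species trends given")
    classes = pd.Series([t.trend_class for t in trends])
    counts = classes.value_counts()
    out = pd.DataFrame({
        "count": counts,
        "proportion": counts / len(trends),
    })
    out.index.name = "trend_class"
    return out.reset_index()


def abundance_change_correlation(trends: list[SpeciesTrend]) -> pd.DataFrame:
    """Pearson correlations of |predictors| with predicted 5-year change:
    total abundance vs change and yearly CV vs change, with t-test p.

    Rows with undefined inputs are dropped; degenerate correlations
    (constant vectors) yield NaN r and p.
    """
    change = np.array([t.change_5yr for t in trends], float)
    abund = np.array([t.total_abundance for t in trends], float)
    cv = np.array([t.yearly_cv for t in trends], float)

    rows = []
    for name, x in (("total_abundance", abund), ("yearly_cv", cv)):
        ok = np.isfinite(x) & np.isfinite(change)
        xi, yi = x[ok], change[ok]
        if len(xi) < 3 or np.std(xi) == 0 or np.std(yi) == 0:
            rows.append({"predictor": name, "r": float("nan"),
                         "p_value": float("nan"), "n": int(len(xi))})
            continue
        r, p = stats.pearsonr(xi, yi)
        rows.append({"predictor": name, "r": float(r),
                     "p_value": float(p), "n": int(len(xi))})
    return pd.DataFrame(rows)
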