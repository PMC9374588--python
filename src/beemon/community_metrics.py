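"""Abundance, richness, inverse-Simpson diversity, evenness, analytic
rarefaction, species accumulation, replicate summaries, and effect sizes.

The replicate structure follows the monitoring design: metrics are
computed per sampling unit, averaged across years (month scheme), then
averaged across the sites within each site group, yielding one replicate
per (site_group, period).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_io import CommunityMatrix, SiteGrouping

__all__ = [
    "inverse_simpson",
    "evenness",
    "rarefied_richness",
    "accumulation_curve",
    "month_summary",
    "year_summary",
    "percent_change",
    "yearly_cv",
]


def inverse_simpson(counts) -> float:
    """Inverse Simpson diversity D = 1 / sum(p_i^2), the effective number
    of equally abundant species. Returns NaN for an all-zero vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    n = c.sum()
    if n == 0:
        return float("nan")
    p = c / n
    return float(1.0 / np.sum(p ** 2))


def evenness(counts, method: str = "simpson") -> float:
    """Evenness of a count vector.

    ``simpson`` (default): inverse-Simpson D divided by richness S, in
    (0, 1], equal to 1 iff all present species are equally abundant.
    ``pielou``: Shannon H divided by ln(S) (J'), with J' = 1 for S = 1.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        return float("nan")
    s = c.size
    if method == "simpson":
        return inverse_simpson(c) / s
    if method == "pielou":
        if s == 1:
            return 1.0
        p = c / c.sum()
        return float(-(p * np.log(p)).sum() / np.log(s))
    raise ValueError(f"unknown evenness method {method!r}")


def rarefied_richness(counts, n: int) -> float:
    """Analytic individual-based rarefaction.

    Expected species count in a random subsample of ``n`` of the N
    individuals: E[S_n] = sum_i [1 - C(N - n_i, n) / C(N, n)]
    (hypergeometric expectation, computed via log-gamma for stability).
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    N = c.sum()
    if n < 1 or n > N:
        raise ValueError(f"subsample size {n} outside 1..{int(N)}")
    # log C(N - n_i, n) - log C(N, n); species with N - n_i < n are certain
    with np.errstate(invalid="ignore"):
        log_top = gammaln(N - c + 1) - gammaln(n + 1) - gammaln(N - c - n + 1)
    log_bot = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
    miss = np.where(N - c < n, 0.0, np.exp(log_top - log_bot))
    return float(np.sum(1.0 - miss))


def accumulation_curve(
    species_labels, n_perm: int = 100, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Individual-based species accumulation curve.

    Mean over ``n_perm`` random orderings of the individuals of the
    cumulative number of distinct species; element k (1-based) is the
    expected richness after k individuals.
    """
    labels = np.asarray(species_labels)
    if labels.size == 0:
        raise ValueError("no individuals")
    rng = rng or np.random.default_rng()
    codes, _ = pd.factorize(labels)
    n = codes.size
    acc = np.zeros(n)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pc = codes[perm]
        first = np.zeros(n, dtype=bool)
        _, first_idx = np.unique(pc, return_index=True)
        first[first_idx] = True
        acc += np.cumsum(first)
    return acc / n_perm


_METRICS = ("abundance", "richness", "diversity", "evenness")


def _unit_metrics(counts: pd.DataFrame, zero_policy: str) -> pd.DataFrame:
    """Per-row abundance/richness/diversity/evenness of a unit x species
    count matrix. Diversity/evenness of all-zero rows follow zero_policy:
    'exclude' -> NaN (dropped from later averaging), 'zero' -> 0."""
    x = counts.to_numpy(dtype=float)
    abundance = x.sum(axis=1)
    richness = (x > 0).sum(axis=1).astype(float)
    div = np.full(len(x), np.nan)
    evn = np.full(len(x), np.nan)
    nz = abundance > 0
    for i in np.nonzero(nz)[0]:
        div[i] = inverse_simpson(x[i])
        evn[i] = evenness(x[i])
    if zero_policy == "zero":
        div[~nz] = 0.0
        evn[~nz] = 0.0
    elif zero_policy != "exclude":
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return pd.DataFrame(
        {
            "abundance": abundance,
            "richness": richness,
            "diversity": div,
            "evenness": evn,
        },
        index=counts.index,
    )


def month_summary(
    month_matrix: CommunityMatrix,
    grouping: SiteGrouping,
    zero_policy: str = "exclude",
) -> pd.DataFrame:
    """Replicate-level biodiversity summary per (site_group, month).

    Metric per (site, year, month) -> mean across years per (site, month)
    -> mean across sites within each group. With 4 groups this yields 4
    replicates per month, each interpretable as the average biodiversity
    value per site for that month.
    """
    if month_matrix.scheme != "month":
        raise ValueError("expected a month-scheme community matrix")
    per_unit = _unit_metrics(month_matrix.counts, zero_policy)
    per_unit = per_unit.reset_index()
    per_unit["site_group"] = per_unit["site_id"].map(grouping.mapping)
    if per_unit["site_group"].isna().any():
        missing = per_unit.loc[per_unit["site_group"].isna(), "site_id"].unique()
        raise ValueError(f"sites without group assignment: {sorted(missing)}")
    by_site_month = (
        per_unit.groupby(["site_id", "site_group", "month"])[list(_METRICS)]
        .mean()  # across years; NaN months excluded per policy
        .reset_index()
    )
    out = (
        by_site_month.groupby(["site_group", "month"])[list(_METRICS)]
        .mean()
        .reset_index()
        .rename(columns={"month": "period"})
    )
    return out


def year_summary(
    year_matrix: CommunityMatrix,
    grouping: SiteGrouping,
    zero_policy: str = "exclude",
) -> pd.DataFrame:
    """Replicate-level summary per (site_group, year): metric per
    (site, year) averaged across the sites within each group."""
    if year_matrix.scheme != "year":
        raise ValueError("expected a year-scheme community matrix")
    per_unit = _unit_metrics(year_matrix.counts, zero_policy).reset_index()
    per_unit["site_group"] = per_unit["site_id"].map(grouping.mapping)
    if per_unit["site_group"].isna().any():
        missing = per_unit.loc[per_unit["site_group"].isna(), "site_id"].unique()
        raise ValueError(f"sites without group assignment: {sorted(missing)}")
    out = (
        per_unit.groupby(["site_group", "year"])[list(_METRICS)]
        .mean()
        .reset_index()
        .rename(columns={"year": "period"})
    )
    return out


def percent_change(m_low: float, m_high: float, m_overall: float) -> float:
    """Percent-change effect size: 100 * (m_high - m_low) / m_overall.

    The difference between a pair of period means divided by the overall
    mean of that variable; sign preserved.
    """
    if m_overall == 0:
        raise ValueError("overall mean is zero; percent change undefined")
    return 100.0 * (m_high - m_low) / m_overall


def yearly_cv(values) -> float:
    """Coefficient of variation across years, in percent (sample SD / mean).

    Returns NaN when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 yearly values for a CV")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)
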