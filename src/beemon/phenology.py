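"""Phenology: seasonality (median capture day-of-year), phenological
breadth (10th–90th percentile span of capture dates), and the
subsampling correction that draws 30 individuals 500 times and averages
the per-draw statistics, so unequal sample sizes across species do not
bias breadth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import SpecimenTable

__all__ = [
    "PhenologyStats",
    "seasonality_raw",
    "breadth_raw",
    "subsampled_phenology",
    "phenology_table",
    "monthly_capture_percentages",
]

#: numpy quantile method; "linear" matches R's default type-7 rule.
QUANTILE_METHOD = "linear"


def seasonality_raw(dates) -> float:
    """Median capture day-of-year (mean of the middle two for even n)."""
    d = np.asarray(dates, dtype=float)
    if d.size == 0:
        raise ValueError("no capture dates")
    return float(np.median(d))


def breadth_raw(dates, method: str = QUANTILE_METHOD) -> float:
    """Span between the 10th and 90th percentiles of capture dates, in
    days (linear-interpolation quantiles by default)."""
    d = np.asarray(dates, dtype=float)
    if d.size == 0:
        raise ValueError("no capture dates")
    q10, q90 = np.quantile(d, [0.1, 0.9], method=method)
    return float(q90 - q10)


@dataclass
class PhenologyStats:
    """Subsampling-corrected phenology of one species."""

    species: str
    n_individuals: int
    seasonality: float
    breadth: float
    n_sub: int
    n_reps: int
    excluded: bool = False
    reason: str = ""
    quantile_method: str = QUANTILE_METHOD


def subsampled_phenology(
    dates,
    n_sub: int = 30,
    n_reps: int = 500,
    rng: np.random.Generator | None = None,
    species: str = "",
    method: str = QUANTILE_METHOD,
) -> PhenologyStats:
    """Average seasonality and breadth over ``n_reps`` random draws of
    ``n_sub`` capture dates without replacement.

    Species with fewer than ``n_sub`` individuals are excluded with a
    reason code rather than estimated. Deterministic given ``rng``.
    """
    d = np.asarray(dates, dtype=float)
    n = d.size
    if n < n_sub:
        return PhenologyStats(species, n, float("nan"), float("nan"),
                              n_sub, n_reps, excluded=True,
                              reason=f"n={n} < n_sub={n_sub}",
                              quantile_method=method)
    rng = rng or np.random.default_rng()
    if n == n_sub:
        sub = np.tile(d, (1, 1))
    else:
        idx = np.argsort(rng.random((n_reps, n)), axis=1)[:, :n_sub]
        sub = d[idx]
    med = float(np.median(sub, axis=1).mean())
    q10 = np.quantile(sub, 0.1, axis=1, method=method)
    q90 = np.quantile(sub, 0.9, axis=1, method=method)
    br = float((q90 - q10).mean())
    return PhenologyStats(species, n, med, br, n_sub, n_reps,
                          quantile_method=method)


def phenology_table(
    specimens: SpecimenTable,
    min_n: int = 30,
    n_sub: int = 30,
    n_reps: int = 500,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-species phenology for all species with >= ``min_n`` individuals.

    Returns a DataFrame (species, family, n, seasonality, breadth); species
    below the threshold are omitted.
    """
    rng = rng or np.random.default_rng()
    df = specimens.records
    fam = df.groupby("species")["family"].first()
    rows = []
    for sp, grp in df.groupby("species"):
        if len(grp) < min_n:
            continue
        st = subsampled_phenology(
            grp["day_of_year"].to_numpy(), n_sub=n_sub, n_reps=n_reps,
            rng=rng, species=sp,
        )
        rows.append({
            "species": sp,
            "family": fam[sp],
            "n": st.n_individuals,
            "seasonality": st.seasonality,
            "breadth": st.breadth,
        })
    out = pd.DataFrame(rows, columns=["species", "family", "n",
                                      "seasonality", "breadth"])
    return out.sort_values("species").reset_index(drop=True)


def monthly_capture_percentages(
    specimens: SpecimenTable, species: list[str] | None = None
) -> pd.DataFrame:
    """Species x month matrix of capture percentages (rows sum to 100):
    the numeric backbone of a phenology heatmap."""
    df = specimens.records
    if species is not None:
        df = df[df["species"].isin(species)]
    tab = pd.crosstab(df["species"], df["month"])
    pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
    return pct
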