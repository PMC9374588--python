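"""Ingest and validation of specimen records, trees and traits; community
matrix construction under the month and year aggregation schemes.

A *specimen table* has one row per captured individual. Community matrices
pool the two traps within each sampling location and emit explicit all-zero
rows for every (site, period) cell of the sampling design, so that
downstream averages across years include zero-capture periods.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SCHEMA",
    "SchemaError",
    "SpecimenTable",
    "SiteGrouping",
    "CommunityMatrix",
    "read_specimens",
    "read_traits",
    "build_month_matrix",
    "build_year_matrix",
    "read_newick",
    "write_newick",
]

#: Default column mapping (canonical field -> file header), matching the
#: deposited dataset's headers.
DEFAULT_SCHEMA: dict[str, str] = {
    "specimen_id": "specimen_id",
    "species": "species",
    "genus": "genus",
    "family": "family",
    "site_id": "site",
    "trap_id": "trap",
    "date": "date",
}

#: Canonical fields that must be mappable in the input file. genus may be
#: derived from the species binomial; family and specimen_id are optional.
REQUIRED_FIELDS = ("species", "site_id", "trap_id", "date")


class SchemaError(ValueError):
    """Raised when required columns cannot be mapped onto the input file."""


@dataclass
class SpecimenTable:
    """Validated specimen-level records.

    Attributes
    ----------
    records : pandas.DataFrame
        One row per retained individual with canonical columns
        ``specimen_id, species, genus, family, site_id, trap_id, date,
        year, month, day_of_year``.
    n_dropped_unidentified : int
        Rows removed for missing/blank species-level identification.
    n_dropped_bad_date : int
        Rows removed for unparseable dates.
    n_dropped_out_of_season : int
        Rows removed because their month fell outside the configured season.
    """

    records: pd.DataFrame
    n_dropped_unidentified: int = 0
    n_dropped_bad_date: int = 0
    n_dropped_out_of_season: int = 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.records["year"].unique())

    def species_totals(self) -> pd.Series:
        """Total individuals per species, descending."""
        return self.records["species"].value_counts()


@dataclass
class SiteGrouping:
    """Mapping from site_id to site_group_id (8 sites -> 4 groups in the
    motivating study; sites closer than 900 m share a group)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("site grouping is empty")

    def group_of(self, site_id: str) -> str:
        return self.mapping[site_id]

    def validate_sites(self, site_ids: Sequence[str]) -> None:
        missing = sorted(set(site_ids) - set(self.mapping))
        if missing:
            raise ValueError(f"sites without a group assignment: {missing}")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))


@dataclass
class CommunityMatrix:
    """Sampling-unit x species count matrix.

    ``counts`` is indexed by a MultiIndex of unit labels — ``(site_id,
    year, month)`` for the month scheme or ``(site_id, year)`` for the
    year scheme — with one column per species. Integer at build time;
    may hold non-negative reals after averaging.
    """

    counts: pd.DataFrame
    scheme: str  # "month" | "year"

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def units(self) -> list[tuple]:
        return list(self.counts.index)

    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per (unit, species) with a count column."""
        long = self.counts.stack().rename("count").reset_index()
        return long


def _normalize_species(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.split().str.join(" ")


def read_specimens(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    season_months: tuple[int, int] = (4, 10),
    max_bad_date_fraction: float = 0.05,
) -> SpecimenTable:
    """Read and validate a delimited specimen table.

    Rows lacking species-level identification (blank/NA species) are
    dropped and counted. Unparseable dates are dropped and counted; the
    read fails if they exceed ``max_bad_date_fraction`` of rows. Records
    whose month falls outside ``season_months`` are dropped and counted.

    Parameters
    ----------
    path : path-like or file-like
        CSV/TSV file. Delimiter is sniffed unless ``sep`` is given.
    schema : mapping, optional
        Canonical field -> column header; defaults to :data:`DEFAULT_SCHEMA`.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    if sep is None:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        raw = pd.read_csv(path, sep=sep, dtype=str)

    missing = [schema[f] for f in REQUIRED_FIELDS if schema[f] not in raw.columns]
    if missing:
        raise SchemaError(
            f"required columns not found in input: {missing}; "
            f"available: {list(raw.columns)}"
        )

    df = pd.DataFrame(index=raw.index)
    for field_name, col in schema.items():
        if col in raw.columns:
            df[field_name] = raw[col]

    # species-level identification filter
    sp = df["species"]
    unidentified = sp.isna() | (sp.astype(str).str.strip() == "")
    n_unid = int(unidentified.sum())
    df = df.loc[~unidentified].copy()
    df["species"] = _normalize_species(df["species"])

    if "genus" not in df.columns or df["genus"].isna().all():
        df["genus"] = df["species"].str.split().str[0]
    else:
        df["genus"] = df["genus"].fillna(df["species"].str.split().str[0]).str.strip()
    if "family" not in df.columns:
        df["family"] = "Unknown"
    df["family"] = df["family"].fillna("Unknown").astype(str).str.strip()
    if "specimen_id" not in df.columns:
        df["specimen_id"] = [f"row{i}" for i in df.index]

    dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    bad = dates.isna()
    n_bad = int(bad.sum())
    if len(df) and n_bad / len(df) > max_bad_date_fraction:
        raise ValueError(
            f"{n_bad}/{len(df)} rows have unparseable dates "
            f"(> {max_bad_date_fraction:.0%} allowed)"
        )
    df = df.loc[~bad].copy()
    dates = dates.loc[~bad]
    df["date"] = dates.dt.date
    df["year"] = dates.dt.year.astype(int)
    df["month"] = dates.dt.month.astype(int)
    df["day_of_year"] = dates.dt.dayofyear.astype(int)

    lo, hi = season_months
    in_season = (df["month"] >= lo) & (df["month"] <= hi)
    n_off = int((~in_season).sum())
    df = df.loc[in_season].reset_index(drop=True)

    if df.empty:
        raise ValueError("no valid specimen records after filtering")

    cols = [
        "specimen_id", "species", "genus", "family",
        "site_id", "trap_id", "date", "year", "month", "day_of_year",
    ]
    return SpecimenTable(
        records=df[cols],
        n_dropped_unidentified=n_unid,
        n_dropped_bad_date=n_bad,
        n_dropped_out_of_season=n_off,
    )


def read_traits(path, *, sep: str | None = None) -> pd.DataFrame:
    """Read a per-species trait table (body_length, social, diet_specialist,
    below_ground_nesting). Binary traits must be coded {0,1}."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "species" not in df.columns:
        raise SchemaError("trait table requires a 'species' column")
    df = df.set_index("species")
    for col in ("social", "diet_specialist", "below_ground_nesting"):
        if col in df.columns:
            vals = set(pd.unique(df[col].dropna()))
            if not vals <= {0, 1}:
                raise ValueError(f"trait '{col}' must be coded 0/1, got {vals}")
    return df


def _season_grid(
    specimens: SpecimenTable, season_months: tuple[int, int]
) -> tuple[list, list, list]:
    sites = sorted(specimens.records["site_id"].unique())
    years = specimens.years
    months = list(range(season_months[0], season_months[1] + 1))
    return sites, years, months


def build_month_matrix(
    specimens: SpecimenTable,
    grouping: SiteGrouping | None = None,
    *,
    season_months: tuple[int, int] = (4, 10),
) -> CommunityMatrix:
    """Counts per (site, year, month), pooled over the traps within a site.

    Every (site, year, season-month) cell of the design is present, all-zero
    rows included, so later per-month averages across years see zero months.
    """
    df = specimens.records
    if df.empty:
        raise ValueError("empty specimen table")
    if grouping is not None:
        grouping.validate_sites(df["site_id"].unique())

    sites, years, months = _season_grid(specimens, season_months)
    species = specimens.species
    tally = (
        df.groupby(["site_id", "year", "month", "species"], observed=True)
        .size()
        .unstack("species", fill_value=0)
    )
    full_index = pd.MultiIndex.from_product(
        [sites, years, months], names=["site_id", "year", "month"]
    )
    counts = tally.reindex(index=full_index, columns=species, fill_value=0).astype(int)
    return CommunityMatrix(counts=counts, scheme="month")


def build_year_matrix(
    specimens: SpecimenTable,
    grouping: SiteGrouping | None = None,
    *,
    season_months: tuple[int, int] = (4, 10),
) -> CommunityMatrix:
    """Counts per (site, year), pooling traps and all months within the year."""
    monthly = build_month_matrix(specimens, grouping, season_months=season_months)
    counts = monthly.counts.groupby(level=["site_id", "year"]).sum()
    return CommunityMatrix(counts=counts, scheme="year")


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Accepts a path or a raw Newick string. Raises ``ValueError`` if any
    non-root edge lacks a branch length.
    """
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"edge leading to {edge.head_node} lacks a branch length"
            )
        if edge.length < 0:
            raise ValueError("negative branch length in input tree")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree to Newick; write to ``path`` if given."""
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
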