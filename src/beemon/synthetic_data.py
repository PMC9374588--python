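"""Synthetic monitoring-data generator with ground truth.

Emulates the statistical structure the analysis assumes: a steep
(lognormal) rank-abundance distribution, species-specific Gaussian
activity windows inside an April–October season, per-species
multiplicative year trends, a sites x traps x weekly-collection design,
and a pure-birth ultrametric genus tree with genus/family membership.

All randomness flows from one master seed through named substreams
(``params``, ``specimens``, ``tree``, ``traits``), so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from ._rng import substream
from .core_io import SpecimenTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_truth",
    "simulate_specimens",
    "simulate_tree",
    "simulate_traits",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic monitoring design.

    ``abundance_mean_log``/``abundance_sd_log`` set the lognormal law for
    per-species peak trap rates; ``peak_day_range`` and ``spread_range``
    bound the uniform draws of each species' Gaussian activity window
    (mean day-of-year and SD in days); ``trend_sd`` is the SD of the
    per-species log-linear year multiplier b_s (``trend_values`` overrides
    the draw); ``trait_effect`` adds ``trait_effect * trait`` to b_s when
    traits are simulated.
    """

    n_species: int = 60
    n_genera: int = 15
    n_families: int = 5
    n_sites: int = 8
    n_groups: int = 4
    traps_per_site: int = 2
    years: tuple[int, ...] = tuple(range(2014, 2020))
    season_days: tuple[int, int] = (91, 304)
    abundance_mean_log: float = -4.0
    abundance_sd_log: float = 2.5
    peak_day_range: tuple[float, float] = (110.0, 285.0)
    spread_range: tuple[float, float] = (10.0, 30.0)
    trend_sd: float = 0.0
    trend_values: Sequence[float] | None = None
    site_effect_sd: float = 0.3
    trait_effect: float = 0.0
    trait_effect_trait: str = "social"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_genera, self.n_families,
               self.n_sites, self.traps_per_site) < 1:
            raise ValueError("all design counts must be positive")
        if self.n_genera > self.n_species:
            raise ValueError("need n_species >= n_genera")
        lo, hi = self.season_days
        if not (1 <= lo < hi <= 366):
            raise ValueError("season_days must lie within 1..366")
        if self.spread_range[0] <= 0:
            raise ValueError("phenology spread must be positive")

    @property
    def site_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sites)]

    def grouping_map(self) -> dict[str, str]:
        """Assign sites to groups round-robin (contiguous blocks)."""
        per = int(np.ceil(self.n_sites / self.n_groups))
        return {
            s: f"G{i // per + 1}" for i, s in enumerate(self.site_ids)
        }


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulated dataset."""

    species: list[str]
    genus: list[str]
    family: list[str]
    peak_rate: np.ndarray        # lambda_s, peak per-trap weekly rate
    peak_day: np.ndarray         # mu_s, day of year
    spread: np.ndarray           # sigma_s, days
    trend: np.ndarray            # b_s, log multiplier per year
    site_effects: np.ndarray     # multiplicative, one per site
    expected_totals: np.ndarray  # analytic E[total individuals] per species
    traits: pd.DataFrame | None = None
    trait_effect: float = 0.0

    def species_by_genus(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sp, g in zip(self.species, self.genus):
            out.setdefault(g, []).append(sp)
        return out

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "genus": self.genus,
                "family": self.family,
                "peak_rate": self.peak_rate,
                "peak_day": self.peak_day,
                "spread": self.spread,
                "trend": self.trend,
                "expected_total": self.expected_totals,
            }
        )


def _genus_names(config: SimConfig) -> list[str]:
    return [f"Genus{g + 1:02d}" for g in range(config.n_genera)]


def _week_starts(config: SimConfig) -> np.ndarray:
    lo, hi = config.season_days
    return np.arange(lo, hi + 1, 7)


def _weekly_kernel(config: SimConfig, peak_day: np.ndarray,
                   spread: np.ndarray) -> np.ndarray:
    """Gaussian activity weight per (species, week) at week midpoints."""
    mids = _week_starts(config) + 3.0
    z = (mids[None, :] - peak_day[:, None]) / spread[:, None]
    return np.exp(-0.5 * z ** 2)


def make_truth(config: SimConfig) -> SimTruth:
    """Draw the per-species and per-site parameters (no specimens yet)."""
    rng = substream(config.seed, "params")
    S = config.n_species

    # skewed multinomial genus sizes so some genera are speciose
    genera = _genus_names(config)
    w = rng.dirichlet(np.full(config.n_genera, 0.6))
    genus_idx = np.sort(rng.choice(config.n_genera, size=S, p=w))
    # every genus keeps at least one chance of appearing; empty genera are
    # legitimate (they stay as bare tips during grafting)
    species = []
    counters = np.zeros(config.n_genera, int)
    for gi in genus_idx:
        counters[gi] += 1
        species.append(f"{genera[gi]} sp{counters[gi]:02d}")
    genus = [genera[gi] for gi in genus_idx]

    fam_of_genus = {
        g: f"Family{(i % config.n_families) + 1}" for i, g in enumerate(genera)
    }
    family = [fam_of_genus[g] for g in genus]

    lam = rng.lognormal(config.abundance_mean_log, config.abundance_sd_log, S)
    mu = rng.uniform(*config.peak_day_range, S)
    sigma = rng.uniform(*config.spread_range, S)
    if config.trend_values is not None:
        b = np.asarray(config.trend_values, dtype=float)
        if b.shape != (S,):
            raise ValueError("trend_values must have length n_species")
    else:
        b = rng.normal(0.0, config.trend_sd, S) if config.trend_sd > 0 else np.zeros(S)
    site_eff = rng.lognormal(0.0, config.site_effect_sd, config.n_sites)

    truth = SimTruth(
        species=species, genus=genus, family=family,
        peak_rate=lam, peak_day=mu, spread=sigma, trend=b,
        site_effects=site_eff,
        expected_totals=np.zeros(S),
    )
    truth.expected_totals = expected_totals(config, truth)
    return truth


def expected_totals(config: SimConfig, truth: SimTruth) -> np.ndarray:
    """Analytic E[total individuals] per species under the Poisson model."""
    years = np.asarray(config.years, float)
    year_factor = np.exp(
        truth.trend[:, None] * (years[None, :] - years[0])
    ).sum(axis=1)
    kernel_sum = _weekly_kernel(config, truth.peak_day, truth.spread).sum(axis=1)
    site_sum = truth.site_effects.sum() * config.traps_per_site
    return truth.peak_rate * year_factor * kernel_sum * site_sum


def simulate_specimens(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[SpecimenTable, SimTruth]:
    """Simulate a specimen table: one row per captured individual.

    Counts per (species, site, trap, year, week) are Poisson with rate
    ``lambda_s * site_i * exp(b_s (y - y0)) * exp(-(d - mu_s)^2 / 2 sigma_s^2)``
    at the week midpoint d; individuals get a uniform capture day within
    the week. Deterministic given ``config.seed``.
    """
    if truth is None:
        truth = make_truth(config)
    if truth.expected_totals.sum() < 1e-9:
        raise ValueError("degenerate config: expected zero captures overall")

    rng = substream(config.seed, "specimens")
    S = config.n_species
    years = np.asarray(config.years)
    week_starts = _week_starts(config)
    W = len(week_starts)
    kern = _weekly_kernel(config, truth.peak_day, truth.spread)  # (S, W)
    year_fac = np.exp(
        truth.trend[:, None] * (years[None, :] - years[0]).astype(float)
    )  # (S, Y)

    # rate tensor (S, sites, Y, W); traps are iid so sample traps_per_site times
    rate = (
        truth.peak_rate[:, None, None, None]
        * truth.site_effects[None, :, None, None]
        * year_fac[:, None, :, None]
        * kern[:, None, None, :]
    )

    frames = []
    sid = 0
    for trap in range(config.traps_per_site):
        counts = rng.poisson(rate)
        s_i, i_i, y_i, w_i = np.nonzero(counts)
        n_each = counts[s_i, i_i, y_i, w_i]
        reps = np.repeat(np.arange(len(s_i)), n_each)
        if len(reps) == 0:
            continue
        doy = week_starts[w_i[reps]] + rng.integers(0, 7, size=len(reps))
        doy = np.minimum(doy, config.season_days[1])
        yr = years[y_i[reps]]
        # leap years shift day-of-year -> calendar month by one day at the
        # season edges; nudge so captures stay inside the season's months
        leap = (yr % 4 == 0) & ((yr % 100 != 0) | (yr % 400 == 0))
        dates = pd.to_datetime(yr * 1000 + doy + leap, format="%Y%j")
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": [f"sim{trap}_{sid + k}" for k in range(len(reps))],
                    "species": np.asarray(truth.species)[s_i[reps]],
                    "genus": np.asarray(truth.genus)[s_i[reps]],
                    "family": np.asarray(truth.family)[s_i[reps]],
                    "site_id": np.asarray(config.site_ids)[i_i[reps]],
                    "trap_id": f"T{trap + 1}",
                    "date": dates.date,
                    "year": yr,
                    "month": dates.month,
                    "day_of_year": dates.dayofyear,
                }
            )
        )
        sid += len(reps)

    if not frames:
        raise ValueError("simulation produced zero captures; increase rates")
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(
        ["year", "day_of_year", "site_id", "trap_id", "species"]
    ).reset_index(drop=True)
    return SpecimenTable(records=records), truth


def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Pure-birth ultrametric genus tree (all tip depths equal).

    Built by successive random pairwise joins at exponentially spaced
    heights; deterministic given ``config.seed``.
    """
    if config.n_genera < 2:
        raise ValueError("need at least 2 genera for a tree")
    rng = substream(config.seed, "tree")
    taxa = dendropy.TaxonNamespace()
    lineages = []
    heights = {}
    for name in _genus_names(config):
        node = dendropy.Node(taxon=taxa.new_taxon(name))
        heights[id(node)] = 0.0
        lineages.append(node)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right = lineages.pop(j)
        left = lineages.pop(i)
        parent = dendropy.Node()
        heights[id(parent)] = t
        for child in (left, right):
            parent.add_child(child)
            child.edge.length = t - heights[id(child)]
        lineages.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = lineages[0]
    tree.is_rooted = True
    return tree


def simulate_traits(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Draw species traits; inject the configured trait effect into b_s.

    Binary traits are Bernoulli(0.5); body length is lognormal (about
    10 mm median). When ``config.trait_effect`` is nonzero the chosen
    trait's (centered) value times the effect is added to ``truth.trend``
    in place, so call this *before* :func:`simulate_specimens`.
    """
    rng = substream(config.seed, "traits")
    S = config.n_species
    traits = pd.DataFrame(
        {
            "species": truth.species,
            "body_length": rng.lognormal(np.log(10.0), 0.3, S),
            "social": rng.integers(0, 2, S),
            "diet_specialist": rng.integers(0, 2, S),
            "below_ground_nesting": rng.integers(0, 2, S),
        }
    ).set_index("species")
    truth.traits = traits
    truth.trait_effect = config.trait_effect
    if config.trait_effect != 0.0:
        x = traits[config.trait_effect_trait].to_numpy(float)
        truth.trend = truth.trend + config.trait_effect * (x - x.mean())
        truth.expected_totals = expected_totals(config, truth)
    return traits


def simulate_dataset(config: SimConfig):
    """Full bundle: (specimens, tree, traits, truth), in the order the
    stages depend on each other."""
    truth = make_truth(config)
    tree = simulate_tree(config)
    traits = simulate_traits(config, truth)
    specimens, truth = simulate_specimens(config, truth)
    return specimens, tree, traits, truth
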