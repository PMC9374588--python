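import numpy as np
import pandas as pd
import pytest

from beemon.core_io import SpecimenTable
from beemon.synthetic_data import SimConfig, simulate_dataset


def make_specimen_df(rows):
    """Build a canonical specimen record frame from compact tuples
    (species, site, trap, date-string)."""
    recs = []
    for i, (species, site, trap, date) in enumerate(rows):
        ts = pd.Timestamp(date)
        recs.append(
            {
                "specimen_id": f"id{i}",
                "species": species,
                "genus": species.split()[0],
                "family": "FamilyX",
                "site_id": site,
                "trap_id": trap,
                "date": ts.date(),
                "year": ts.year,
                "month": ts.month,
                "day_of_year": ts.dayofyear,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def specimen_table_factory():
    def _make(rows):
        return SpecimenTable(records=make_specimen_df(rows))

    return _make


@pytest.fixture(scope="session")
def default_sim():
    """One realization of the default simulator (shared across tests)."""
    return simulate_dataset(SimConfig(seed=3))


@pytest.fixture(scope="session")
def small_sim():
    """A lighter simulated dataset for pipeline-level tests."""
    cfg = SimConfig(
        n_species=25, n_genera=8, seed=11,
        abundance_mean_log=-2.0, abundance_sd_log=1.5,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
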