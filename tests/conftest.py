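import numpy as np
import pandas as pd
import pytest

from befstab.data_model import Dataset
from befstab.synthetic_data import SimulationConfig


def make_config(**kw) -> SimulationConfig:
    """Small-but-structured simulation config for fast tests."""
    defaults = dict(
        replicates={1: 16, 4: 5, 9: 4, 16: 3},
        n_years=10,
        n_excluded_precip=0,
        n_excluded_warming=0,
        f_unsorted=0.0,
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def toy_dataset(unsorted_years=(), extra_obs=None) -> Dataset:
    """Two plots (one monoculture, one 2-species mixture), 3 species, 4 years.

    ``unsorted_years``: (plot_id, year) pairs to blank out to community
    totals only.  ``extra_obs``: rows appended verbatim (to force violations).
    """
    species = pd.DataFrame(
        {
            "species_id": ["spA", "spB", "spC"],
            "functional_group": ["C3 grass", "legume", "forb"],
        }
    )
    plots = pd.DataFrame(
        {
            "plot_id": ["P1", "P2"],
            "ring_id": [1, 1],
            "co2": ["ambient", "ambient"],
            "nitrogen": ["ambient", "enriched"],
            "planted_richness": [1, 2],
            "planted_species": ["spA", "spA;spB"],
            "excluded": [False, False],
            "exclusion_reason": [pd.NA, pd.NA],
        }
    )
    rows = []
    for year in (2000, 2001, 2002, 2003):
        rows.append(dict(plot_id="P1", year=year, species_id="spA",
                         biomass=40.0 + year % 4, cover=20.0, sorted=True))
        for sid, b in (("spA", 25.0 + year % 3), ("spB", 10.0 + year % 2)):
            rows.append(dict(plot_id="P2", year=year, species_id=sid,
                             biomass=b, cover=b / 2.0, sorted=True))
    obs = pd.DataFrame(rows)
    if extra_obs is not None:
        obs = pd.concat([obs, pd.DataFrame(extra_obs)], ignore_index=True)
    totals = (
        obs[obs["sorted"]]
        .groupby(["plot_id", "year"], as_index=False)["biomass"]
        .sum()
        .rename(columns={"biomass": "total_biomass"})
    )
    for plot_id, year in unsorted_years:
        mask = (obs["plot_id"] == plot_id) & (obs["year"] == year)
        obs.loc[mask, "biomass"] = np.nan
        obs.loc[mask, "sorted"] = False
    return Dataset(species, plots, obs, totals)


@pytest.fixture
def toy():
    return toy_dataset()


@pytest.fixture
def small_sim():
    from befstab.synthetic_data import simulate_dataset

    return simulate_dataset(make_config())
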