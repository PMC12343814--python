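"""Synthetic split-plot community data with known ground truth.

The generator emulates the statistical structure of a FACE-style grassland
biodiversity experiment: six rings carrying a whole-plot CO2 treatment
(half elevated), sub-plot nitrogen addition, planted richness levels
{1, 4, 9, 16} drawn from a 16-species pool in four functional groups, and
24 annual biomass/cover censuses.  It is NOT a mechanistic population model;
it targets exactly the quantities the downstream partitions estimate:

* expected mixture biomass of species *i* at planted richness *N* is
  ``mu_i * (1/N + dRY_i)`` with relative-yield deviation

      dRY_i = delta_CE(N)/N + delta_SE * (mu_i - mean(mu))/mean(mu)

  so the complementarity coefficient ``delta_CE`` and the
  dominance-covariance coefficient ``delta_SE`` independently control the
  expected complementarity and selection effects of the additive partition;
* inter-annual variation is a species loading ``lambda_i`` on a mixture of a
  shared annual shock and independent species shocks with weight
  ``rho_sync`` in [0, 1]; ``rho_sync = 1`` with equal loadings gives
  perfectly proportional species series (asynchrony = 1);
* multiplicative lognormal observation noise ``sigma_obs`` (mean-one);
* percent cover proportional to biomass (species slope ``cover_slope_i`` in
  g m^-2 per percent) with its own mean-one lognormal noise;
* a fraction ``f_unsorted`` of mixture plot-years emitted with the community
  total only (species biomass withheld, cover retained), feeding the
  gap-filling stage; monoculture plot-years are always sorted.

Every plot owns an RNG stream derived from ``(seed, plot_id)`` so any subset
of plots regenerates identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from befstab.data_model import (
    CO2_LEVELS,
    FUNCTIONAL_GROUPS,
    N_LEVELS,
    ConfigError,
    Dataset,
)

# default per-(CO2 x N) replicate allocation across richness levels; the four
# treatment combinations then total 4 x (32+15+15+12) = 296 plots.
DEFAULT_REPLICATES = {1: 32, 4: 15, 9: 15, 16: 12}

DEFAULT_CO2_MULT = {"C3 grass": 1.15, "C4 grass": 1.05, "legume": 1.10, "forb": 1.05}
DEFAULT_N_MULT = {"C3 grass": 1.25, "C4 grass": 1.10, "legume": 0.95, "forb": 1.10}


def _stream(seed: int, *keys) -> np.random.Generator:
    ints = [seed] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Biomass units are g m^-2 throughout; cover is percent of quadrat area.
    ``delta_ce(N) = ce_base + ce_log_richness_slope * ln(N)`` lets the
    complementarity signal grow with planted richness, the structure the
    analysis is designed to detect; set the slope to 0 for a richness-flat
    effect and both to 0 for a null community.
    """

    n_rings: int = 6
    elevated_fraction: float = 0.5
    replicates: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    n_species: int = 16
    n_years: int = 24
    start_year: int = 1998
    seed: int = 0

    # monoculture means mu_i (g m^-2); default geometric spread over the pool
    mu: np.ndarray | None = None
    ce_base: float = 0.0
    ce_log_richness_slope: float = 0.25
    delta_se: float = -0.02
    rho_sync: float = 0.5
    lambda_loading: float = 0.40
    sigma_obs: float = 0.15
    co2_multiplier: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CO2_MULT))
    n_multiplier: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_N_MULT))
    # cover model: biomass = cover_slope_i * cover; default slope mu_i / 50
    cover_slope: np.ndarray | None = None
    sigma_cover: float = 0.10
    f_unsorted: float = 0.12
    n_excluded_precip: int = 24
    n_excluded_warming: int = 12

    def __post_init__(self):
        if self.mu is None:
            self.mu = np.geomspace(40.0, 320.0, self.n_species)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.cover_slope is None:
            self.cover_slope = self.mu / 50.0
        self.cover_slope = np.asarray(self.cover_slope, dtype=float)
        if not (0.0 <= self.rho_sync <= 1.0):
            raise ConfigError("rho_sync must lie in [0, 1]")
        if self.sigma_obs < 0 or self.sigma_cover < 0:
            raise ConfigError("noise SDs must be nonnegative")
        if not (0.0 <= self.f_unsorted < 1.0):
            raise ConfigError("f_unsorted must lie in [0, 1)")
        if (self.mu <= 0).any():
            raise ConfigError("monoculture means mu must be positive")
        if max(self.replicates) > self.n_species:
            raise ConfigError(
                f"richness {max(self.replicates)} exceeds pool size {self.n_species}"
            )

    def delta_ce(self, richness: int) -> float:
        return self.ce_base + self.ce_log_richness_slope * np.log(richness)


@dataclass
class GroundTruth:
    """Noise-free expectations emitted alongside each simulated dataset."""

    expected: pd.DataFrame  # plot_id, year, species_id, expected_biomass
    plot_summary: pd.DataFrame  # plot_id, richness, delta_ce, delta_se, expected_dY, sign
    rho_sync: float
    seed: int


def _species_table(config: SimulationConfig) -> pd.DataFrame:
    groups = [FUNCTIONAL_GROUPS[(i * 4) // config.n_species] for i in range(config.n_species)]
    return pd.DataFrame(
        {
            "species_id": [f"sp{i + 1:02d}" for i in range(config.n_species)],
            "functional_group": groups,
        }
    )


def generate_design(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out plots across rings and sample planted compositions.

    Returns (plots, species) tables.  CO2 is constant per ring; each
    (CO2, N) treatment cell receives the replicate table's plot counts,
    distributed round-robin over that CO2 level's rings.  Exclusion flags
    for the precipitation/warming sub-experiments are assigned to a seeded
    random subset of plots.
    """
    species = _species_table(config)
    pool = species["species_id"].to_numpy()

    n_elev = int(round(config.n_rings * config.elevated_fraction))
    ring_co2 = {r: ("elevated" if r <= n_elev else "ambient") for r in range(1, config.n_rings + 1)}
    rings_by_co2 = {
        lvl: [r for r in ring_co2 if ring_co2[r] == lvl] for lvl in CO2_LEVELS
    }
    for lvl, rr in rings_by_co2.items():
        if not rr:
            raise ConfigError(f"no rings assigned to CO2 level '{lvl}'")

    rows = []
    counter = {r: 0 for r in ring_co2}
    for co2 in CO2_LEVELS:
        rings = rings_by_co2[co2]
        for nitrogen in N_LEVELS:
            for richness in sorted(config.replicates):
                # monocultures cycle through a per-cell shuffle of the pool so
                # every species is represented as evenly as the replicate count
                # allows (the usual design for monoculture reference plots)
                if richness == 1:
                    cell_rng = _stream(config.seed, co2, nitrogen, "mono-order")
                    mono_order = cell_rng.permutation(pool)
                for k in range(config.replicates[richness]):
                    ring = rings[k % len(rings)]
                    counter[ring] += 1
                    plot_id = f"R{ring}P{counter[ring]:03d}"
                    if richness == 1:
                        comp = np.array([mono_order[k % len(pool)]])
                    else:
                        comp_rng = _stream(config.seed, plot_id, "composition")
                        comp = np.sort(comp_rng.choice(pool, size=richness, replace=False))
                    rows.append(
                        {
                            "plot_id": plot_id,
                            "ring_id": ring,
                            "co2": co2,
                            "nitrogen": nitrogen,
                            "planted_richness": richness,
                            "planted_species": ";".join(comp),
                            "excluded": False,
                            "exclusion_reason": pd.NA,
                        }
                    )
    plots = pd.DataFrame(rows)

    n_flag = config.n_excluded_precip + config.n_excluded_warming
    if n_flag:
        flag_rng = _stream(config.seed, "exclusions")
        idx = flag_rng.choice(len(plots), size=min(n_flag, len(plots)), replace=False)
        precip = idx[: config.n_excluded_precip]
        warming = idx[config.n_excluded_precip :]
        plots.loc[precip, ["excluded", "exclusion_reason"]] = [True, "precipitation"]
        plots.loc[warming, ["excluded", "exclusion_reason"]] = [True, "warming"]
    return plots, species


def simulate_dynamics(
    plots: pd.DataFrame, species: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw species-year biomass and cover for every plot.

    Returns (observations, totals, ground_truth).  Community totals are the
    species sums of the *observed* (noisy) biomass, so with ``sigma_obs = 0``
    and ``f_unsorted = 0`` totals equal species sums exactly.
    """
    years = np.arange(config.start_year, config.start_year + config.n_years)
    mu_by_sp = dict(zip(species["species_id"], config.mu))
    slope_by_sp = dict(zip(species["species_id"], config.cover_slope))
    fg_by_sp = dict(zip(species["species_id"], species["functional_group"]))

    # shared annual environment, common to all plots
    eta = _stream(config.seed, "annual-environment").standard_normal(config.n_years)
    lam = config.lambda_loading
    w_shared = np.sqrt(config.rho_sync)
    w_indep = np.sqrt(1.0 - config.rho_sync)

    obs_rows, tot_rows, truth_rows, summary_rows = [], [], [], []
    for row in plots.itertuples():
        comp = row.planted_species.split(";")
        N = len(comp)
        mu_vec = np.array([mu_by_sp[s] for s in comp])
        mu_bar = mu_vec.mean()
        mult = np.array(
            [
                (config.co2_multiplier[fg_by_sp[s]] if row.co2 == "elevated" else 1.0)
                * (config.n_multiplier[fg_by_sp[s]] if row.nitrogen == "enriched" else 1.0)
                for s in comp
            ]
        )
        if N == 1:
            drys = np.zeros(1)
            d_ce = 0.0
        else:
            d_ce = config.delta_ce(N)
            drys = d_ce / N + config.delta_se * (mu_vec - mu_bar) / mu_bar
        expected_mean = mu_vec * (1.0 / N + drys) * mult  # per-species, per-year expectation

        rng = _stream(config.seed, row.plot_id, "dynamics")
        indep = rng.standard_normal((config.n_years, N))
        shock = lam * (w_shared * eta[:, None] + w_indep * indep)
        surface = expected_mean[None, :] * np.exp(shock - 0.5 * lam**2)

        if config.sigma_obs > 0:
            noise = np.exp(
                config.sigma_obs * rng.standard_normal((config.n_years, N))
                - 0.5 * config.sigma_obs**2
            )
        else:
            noise = 1.0
        biomass = surface * noise

        cover_slopes = np.array([slope_by_sp[s] for s in comp])
        if config.sigma_cover > 0:
            cnoise = np.exp(
                config.sigma_cover * rng.standard_normal((config.n_years, N))
                - 0.5 * config.sigma_cover**2
            )
        else:
            cnoise = 1.0
        cover = np.clip(biomass / cover_slopes[None, :] * cnoise, 0.0, 100.0)

        unsorted_years = np.zeros(config.n_years, dtype=bool)
        if N > 1 and config.f_unsorted > 0:
            unsorted_years = rng.random(config.n_years) < config.f_unsorted

        for t, year in enumerate(years):
            total = float(biomass[t].sum())
            tot_rows.append({"plot_id": row.plot_id, "year": int(year), "total_biomass": total})
            is_sorted = not unsorted_years[t]
            for j, sid in enumerate(comp):
                obs_rows.append(
                    {
                        "plot_id": row.plot_id,
                        "year": int(year),
                        "species_id": sid,
                        "biomass": float(biomass[t, j]) if is_sorted else np.nan,
                        "cover": float(cover[t, j]),
                        "sorted": is_sorted,
                    }
                )
                truth_rows.append(
                    {
                        "plot_id": row.plot_id,
                        "year": int(year),
                        "species_id": sid,
                        "expected_biomass": float(surface[t, j]),
                    }
                )
        # expected net biodiversity effect against matched monoculture means
        expected_dy = float(np.sum(drys * mu_vec * mult))
        summary_rows.append(
            {
                "plot_id": row.plot_id,
                "richness": N,
                "delta_ce": d_ce,
                "delta_se": config.delta_se if N > 1 else 0.0,
                "expected_dY": expected_dy,
                "expected_dY_sign": int(np.sign(expected_dy)),
            }
        )

    truth = GroundTruth(
        expected=pd.DataFrame(truth_rows),
        plot_summary=pd.DataFrame(summary_rows),
        rho_sync=config.rho_sync,
        seed=config.seed,
    )
    return pd.DataFrame(obs_rows), pd.DataFrame(tot_rows), truth


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Full generator: design + dynamics, returned as a validated Dataset."""
    plots, species = generate_design(config)
    observations, totals, truth = simulate_dynamics(plots, species, config)
    ds = Dataset(species, plots, observations, totals)
    return ds, truth
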