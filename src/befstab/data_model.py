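"""Canonical data types, validation and IO for long-format experiment tables.

The interchange format is a set of four tidy CSV tables:

``species``
    one row per species: ``species_id``, ``functional_group``.
``plots``
    one row per plot: ``plot_id``, ``ring_id``, ``co2`` (ambient/elevated),
    ``nitrogen`` (ambient/enriched), ``planted_richness``,
    ``planted_species`` (semicolon-joined species ids), ``excluded``
    (true/false) and ``exclusion_reason``.
``observations``
    one row per plot-year-species: ``plot_id``, ``year``, ``species_id``,
    ``biomass`` (g m^-2, empty if not sorted to species), ``cover``
    (percent, empty if not recorded), ``sorted`` (true/false).
``totals``
    one row per plot-year: ``plot_id``, ``year``, ``total_biomass``.

Unsorted plot-years (community total weighed but biomass not sorted to
species) carry observation rows with ``sorted = false`` and missing biomass;
their cover values drive the gap-filling step.  An absent cover cell means
"not recorded"; an explicit 0 means "observed absent".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

FUNCTIONAL_GROUPS = ("C3 grass", "C4 grass", "legume", "forb")
CO2_LEVELS = ("ambient", "elevated")
N_LEVELS = ("ambient", "enriched")
RICHNESS_LEVELS = (1, 4, 9, 16)

#: canonical column names per table
SCHEMA = {
    "species": ["species_id", "functional_group"],
    "plots": [
        "plot_id",
        "ring_id",
        "co2",
        "nitrogen",
        "planted_richness",
        "planted_species",
        "excluded",
        "exclusion_reason",
    ],
    "observations": ["plot_id", "year", "species_id", "biomass", "cover", "sorted"],
    "totals": ["plot_id", "year", "total_biomass"],
}

TOTAL_TOLERANCE = 1e-6  # relative tolerance for total == sum(species) checks


class SchemaError(ValueError):
    """A table is missing mandatory columns or has the wrong shape."""


class ValidationError(ValueError):
    """Table contents violate a dataset invariant."""


class ConfigError(ValueError):
    """An analysis or simulation configuration is inconsistent."""


@dataclass
class ValidationReport:
    n_species: int
    n_plots: int
    n_excluded_plots: int
    exclusions_by_reason: dict
    n_observations: int
    n_plot_years: int
    n_unsorted_plot_years: int
    year_range: tuple

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["year_range"] = list(d["year_range"])
        return json.dumps(d, indent=2)


@dataclass
class Dataset:
    """In-memory dataset: four aligned pandas tables.

    ``planted`` maps plot_id -> frozenset of planted species ids (derived
    from the plots table; kept as an attribute so downstream stages do not
    re-parse the semicolon encoding).
    """

    species: pd.DataFrame
    plots: pd.DataFrame
    observations: pd.DataFrame
    totals: pd.DataFrame
    planted: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.planted:
            self.planted = {
                row.plot_id: frozenset(str(row.planted_species).split(";"))
                for row in self.plots.itertuples()
            }

    def copy(self) -> "Dataset":
        return Dataset(
            self.species.copy(),
            self.plots.copy(),
            self.observations.copy(),
            self.totals.copy(),
        )

    def unsorted_plot_years(self) -> pd.DataFrame:
        """Plot-years whose species biomass was not sorted (to be imputed)."""
        obs = self.observations
        flag = obs.groupby(["plot_id", "year"])["sorted"].any()
        return flag[~flag].reset_index()[["plot_id", "year"]]

    def validate(self) -> ValidationReport:
        return validate_dataset(self)


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in SCHEMA[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{table}' is missing columns {missing}")


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Check every invariant; raise a typed error or return the report."""
    for name in SCHEMA:
        _require_columns(getattr(ds, name if name != "species" else "species"), name)

    sp = ds.species
    if sp["species_id"].duplicated().any():
        dups = sorted(sp.loc[sp["species_id"].duplicated(), "species_id"])
        raise ValidationError(f"duplicate species ids: {dups}")
    bad_fg = sorted(set(sp["functional_group"]) - set(FUNCTIONAL_GROUPS))
    if bad_fg:
        raise ValidationError(f"unknown functional groups: {bad_fg}")

    pl = ds.plots
    if pl["plot_id"].duplicated().any():
        raise ValidationError("duplicate plot ids")
    bad_co2 = sorted(set(pl["co2"]) - set(CO2_LEVELS))
    if bad_co2:
        raise ValidationError(f"unknown CO2 levels: {bad_co2}")
    bad_n = sorted(set(pl["nitrogen"]) - set(N_LEVELS))
    if bad_n:
        raise ValidationError(f"unknown nitrogen levels: {bad_n}")
    # whole-plot factor: CO2 constant within a ring
    ring_levels = pl.groupby("ring_id")["co2"].nunique()
    mixed = sorted(ring_levels[ring_levels > 1].index)
    if mixed:
        raise ValidationError(f"CO2 varies within ring(s) {mixed}: it is a whole-plot factor")
    # richness vs composition
    bad = []
    for row in pl.itertuples():
        planted = ds.planted[row.plot_id]
        if len(planted) != row.planted_richness:
            bad.append((row.plot_id, row.planted_richness, len(planted)))
    if bad:
        raise ValidationError(
            "planted_richness does not match |planted_species| for plots: " + repr(bad)
        )
    unknown_sp = set().union(*ds.planted.values()) - set(sp["species_id"])
    if unknown_sp:
        raise ValidationError(f"planted species absent from species table: {sorted(unknown_sp)}")

    obs = ds.observations
    if (obs["biomass"].dropna() < 0).any():
        n = int((obs["biomass"].dropna() < 0).sum())
        raise ValidationError(f"{n} negative biomass value(s)")
    cov = obs["cover"].dropna()
    if ((cov < 0) | (cov > 100)).any():
        raise ValidationError("cover values outside [0, 100]")
    unsorted_with_biomass = obs[(~obs["sorted"].astype(bool)) & obs["biomass"].notna()]
    if len(unsorted_with_biomass):
        raise ValidationError(
            f"{len(unsorted_with_biomass)} unsorted observation(s) carry species biomass"
        )
    # species must be planted in their plot
    offenders = []
    for (plot_id,), grp in obs.groupby(["plot_id"]):
        planted = ds.planted.get(plot_id)
        if planted is None:
            raise ValidationError(f"observations reference unknown plot '{plot_id}'")
        extra = set(grp["species_id"]) - planted
        if extra:
            offenders.append((plot_id, sorted(extra)))
    if offenders:
        raise ValidationError(
            "species observed in plots where they were not planted: " + repr(offenders)
        )

    tot = ds.totals
    if (tot["total_biomass"] < 0).any():
        raise ValidationError("negative community total biomass")
    if tot.duplicated(["plot_id", "year"]).any():
        raise ValidationError("duplicate plot-year rows in totals")

    # sorted plot-years: total equals the species sum
    sorted_sum = (
        obs[obs["sorted"].astype(bool)]
        .groupby(["plot_id", "year"])["biomass"]
        .sum(min_count=1)
        .rename("species_sum")
    )
    merged = tot.merge(sorted_sum, on=["plot_id", "year"], how="inner")
    mismatch = merged[
        ~np.isclose(
            merged["total_biomass"],
            merged["species_sum"],
            rtol=TOTAL_TOLERANCE,
            atol=1e-6,
        )
    ]
    if len(mismatch):
        first = mismatch.iloc[0]
        raise ValidationError(
            f"{len(mismatch)} sorted plot-year(s) where total != sum(species biomass); "
            f"first offender plot {first['plot_id']} year {int(first['year'])}: "
            f"{first['total_biomass']:.4f} vs {first['species_sum']:.4f}"
        )

    excl = pl[pl["excluded"].astype(bool)]
    by_reason = excl["exclusion_reason"].fillna("unspecified").value_counts().to_dict()
    years = obs["year"]
    return ValidationReport(
        n_species=len(sp),
        n_plots=len(pl),
        n_excluded_plots=len(excl),
        exclusions_by_reason={str(k): int(v) for k, v in by_reason.items()},
        n_observations=len(obs),
        n_plot_years=int(obs.groupby(["plot_id", "year"]).ngroups),
        n_unsorted_plot_years=len(ds.unsorted_plot_years()),
        year_range=(int(years.min()), int(years.max())) if len(years) else (0, 0),
    )


def read_dataset(
    directory,
    column_map: dict | None = None,
    year_range: tuple | None = None,
    validate: bool = True,
) -> Dataset:
    """Read the four CSV tables from ``directory`` and validate.

    Parameters
    ----------
    directory : path containing species.csv, plots.csv, observations.csv,
        totals.csv (names overridable through ``column_map['files']``).
    column_map : optional nested mapping ``{table: {canonical: actual}}``
        adapting foreign column names; may also carry a ``files`` entry
        mapping table name to file name.
    year_range : optional (first, last) inclusive analysis window applied to
        observations and totals.
    """
    directory = Path(directory)
    column_map = column_map or {}
    files = column_map.get("files", {})
    frames = {}
    for table in SCHEMA:
        path = directory / files.get(table, f"{table}.csv")
        if not path.exists():
            raise SchemaError(f"missing table file: {path}")
        df = pd.read_csv(path)
        mapping = {v: k for k, v in column_map.get(table, {}).items()}
        df = df.rename(columns=mapping)
        _require_columns(df, table)
        frames[table] = df[SCHEMA[table]]

    frames["plots"] = frames["plots"].assign(
        excluded=frames["plots"]["excluded"].astype(bool),
        exclusion_reason=frames["plots"]["exclusion_reason"].astype("string"),
    )
    frames["observations"] = frames["observations"].assign(
        sorted=frames["observations"]["sorted"].astype(bool)
    )
    if year_range is not None:
        lo, hi = year_range
        frames["observations"] = frames["observations"].query("@lo <= year <= @hi")
        frames["totals"] = frames["totals"].query("@lo <= year <= @hi")
    ds = Dataset(
        frames["species"].reset_index(drop=True),
        frames["plots"].reset_index(drop=True),
        frames["observations"].reset_index(drop=True),
        frames["totals"].reset_index(drop=True),
    )
    if validate:
        validate_dataset(ds)
    return ds


def write_dataset(ds: Dataset, directory) -> None:
    """Write the four tables as CSV; inverse of :func:`read_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ds.species.to_csv(directory / "species.csv", index=False)
    ds.plots.to_csv(directory / "plots.csv", index=False)
    ds.observations.to_csv(directory / "observations.csv", index=False)
    ds.totals.to_csv(directory / "totals.csv", index=False)


def filter_analysis_plots(ds: Dataset, log=None) -> Dataset:
    """Drop plots flagged excluded (e.g. precipitation/warming sub-treatments).

    Returns a new dataset restricted to analysis plots; removal counts by
    reason are passed to ``log`` (a callable taking one string) if given.
    """
    pl = ds.plots
    excluded = pl[pl["excluded"].astype(bool)]
    if log is not None:
        for reason, n in excluded["exclusion_reason"].fillna("unspecified").value_counts().items():
            log(f"excluding {n} plot(s): {reason}")
        if len(pl) == len(excluded):
            log("warning: all plots excluded; empty analysis set")
    keep = set(pl.loc[~pl["excluded"].astype(bool), "plot_id"])
    out = Dataset(
        ds.species.copy(),
        pl[pl["plot_id"].isin(keep)].reset_index(drop=True),
        ds.observations[ds.observations["plot_id"].isin(keep)].reset_index(drop=True),
        ds.totals[ds.totals["plot_id"].isin(keep)].reset_index(drop=True),
    )
    return out
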