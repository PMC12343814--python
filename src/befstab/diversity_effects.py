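"""Additive partition of the net biodiversity effect (Loreau-Hector).

For a mixture planted with N species, with Y_i the across-years mean biomass
of species i in the mixture and M_i its across-years mean monoculture
biomass,

    dRY_i = Y_i / M_i - 1/N                 (relative-yield deviation)
    dY    = sum_i dRY_i * M_i               (net biodiversity effect)
    CE    = N * mean(dRY) * mean(M)         (complementarity effect)
    SE    = N * cov_pop(dRY, M)             (selection effect)

with the population (1/k) covariance, under which dY = CE + SE holds as an
algebraic identity.  Monoculture references pool plot-year biomasses within
each species x CO2 x N treatment cell after dropping plot-years below a
biomass threshold (default 2.5 g m^-2), because relative yields blow up as
the monoculture denominator approaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from befstab.data_model import Dataset

MONOCULTURE_THRESHOLD = 2.5  # g m^-2


@dataclass
class MonocultureReference:
    species_id: str
    co2: str
    nitrogen: str
    mean_biomass: float  # M_i
    n_plot_years: int


@dataclass
class PartitionResult:
    plot_id: str
    richness: int  # planted N
    delta_y: float
    ce: float
    se: float
    species: pd.DataFrame  # species_id, Y_i, M_i, dRY_i
    dropped_species: list = field(default_factory=list)  # no valid M_i

    def as_row(self) -> dict:
        return {
            "plot_id": self.plot_id,
            "richness": self.richness,
            "delta_y": self.delta_y,
            "ce": self.ce,
            "se": self.se,
            "n_retained": len(self.species),
            "n_dropped": len(self.dropped_species),
        }


class PartitionUndefinedError(ValueError):
    """Fewer than two species with a valid monoculture reference."""


def monoculture_reference(
    ds: Dataset,
    threshold: float = MONOCULTURE_THRESHOLD,
    pool_treatments: bool = False,
) -> dict:
    """Temporal-mean monoculture biomass per species (x treatment cell).

    Monoculture plot-year biomasses below ``threshold`` are discarded before
    averaging; a reference is absent (not zero) when nothing survives.
    With ``pool_treatments`` the CO2 x N stratification is collapsed — a
    sensitivity option; the default matches each mixture to monocultures
    grown under its own treatment combination.

    Returns ``{(species_id, co2, nitrogen): MonocultureReference}`` (the
    treatment keys are ``"*"`` when pooled).
    """
    mono_plots = ds.plots[ds.plots["planted_richness"] == 1]
    meta = mono_plots.set_index("plot_id")[["co2", "nitrogen"]]
    obs = ds.observations
    obs = obs[obs["plot_id"].isin(meta.index) & obs["biomass"].notna()]
    obs = obs.join(meta, on="plot_id")
    obs = obs[obs["biomass"] >= threshold]
    if pool_treatments:
        obs = obs.assign(co2="*", nitrogen="*")
    refs = {}
    for (sid, co2, nit), grp in obs.groupby(["species_id", "co2", "nitrogen"]):
        refs[(str(sid), str(co2), str(nit))] = MonocultureReference(
            str(sid), str(co2), str(nit), float(grp["biomass"].mean()), len(grp)
        )
    return refs


def mixture_species_means(ds: Dataset, plot_id: str) -> pd.Series:
    """Across-years mean biomass per planted species in one plot.

    Planted species with no biomass record in a year contribute zero for
    that year (absence is information); unplanted species never enter.
    """
    obs = ds.observations
    sub = obs[(obs["plot_id"] == plot_id)]
    years = sub["year"].unique()
    planted = sorted(ds.planted[plot_id])
    wide = (
        sub.pivot_table(index="year", columns="species_id", values="biomass", aggfunc="sum")
        .reindex(index=sorted(years), columns=planted)
        .fillna(0.0)
    )
    return wide.mean(axis=0)


def additive_partition(
    richness: int,
    mixture_means: pd.Series,
    references: dict,
    co2: str = "*",
    nitrogen: str = "*",
    plot_id: str = "",
) -> PartitionResult:
    """Partition dY into CE and SE for one mixture plot.

    ``mixture_means`` maps species_id -> Y_i.  The expected relative yield
    is 1/planted-richness for every species (even seeding), including when
    some species are dropped for lack of a monoculture reference — dropped
    species simply leave the sums.  The multiplier in the CE/SE formulas is
    the number of species actually retained (equal to planted richness
    whenever nothing is dropped): dY = CE + SE is an algebraic identity
    only for that count, and the partition stands or falls by it.
    """
    if richness < 2:
        raise PartitionUndefinedError("additive partition needs a mixture (N >= 2)")
    N = richness
    rows, dropped = [], []
    for sid, y_i in mixture_means.items():
        ref = references.get((sid, co2, nitrogen)) or references.get((sid, "*", "*"))
        if ref is None:
            dropped.append(sid)
            continue
        m_i = ref.mean_biomass
        assert m_i > 0, "threshold filter guarantees positive monoculture means"
        rows.append({"species_id": sid, "Y_i": float(y_i), "M_i": m_i, "dRY_i": y_i / m_i - 1.0 / N})
    if len(rows) < 2:
        raise PartitionUndefinedError(
            f"plot {plot_id!r}: only {len(rows)} species with a valid monoculture reference"
        )
    tab = pd.DataFrame(rows)
    dry = tab["dRY_i"].to_numpy()
    m = tab["M_i"].to_numpy()
    k = len(tab)  # retained species count; == N when nothing dropped
    delta_y = float(np.sum(dry * m))
    ce = float(k * dry.mean() * m.mean())
    se = float(k * np.mean((dry - dry.mean()) * (m - m.mean())))  # population covariance
    assert abs(delta_y - (ce + se)) <= 1e-9 * max(1.0, abs(delta_y)), "additive identity"
    return PartitionResult(plot_id, N, delta_y, ce, se, tab, dropped)


def partition_all_mixtures(
    ds: Dataset,
    threshold: float = MONOCULTURE_THRESHOLD,
    pool_treatments: bool = False,
) -> pd.DataFrame:
    """Per-plot dY/CE/SE table for every mixture plot in the dataset.

    Plots whose partition is undefined (fewer than two species with a valid
    monoculture reference) are skipped; the count is in ``attrs``.
    """
    refs = monoculture_reference(ds, threshold=threshold, pool_treatments=pool_treatments)
    rows, skipped = [], []
    mixtures = ds.plots[ds.plots["planted_richness"] > 1]
    for plot in mixtures.itertuples():
        means = mixture_species_means(ds, plot.plot_id)
        co2, nit = ("*", "*") if pool_treatments else (plot.co2, plot.nitrogen)
        try:
            res = additive_partition(
                plot.planted_richness, means, refs, co2, nit, plot.plot_id
            )
        except PartitionUndefinedError:
            skipped.append(plot.plot_id)
            continue
        rows.append(res.as_row())
    out = pd.DataFrame(rows)
    out.attrs["skipped_plots"] = skipped
    return out
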