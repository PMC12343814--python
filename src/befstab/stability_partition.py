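"""Multiplicative partition of community temporal stability.

For a plot observed over T years with species-year biomass y_{i,t}:

    Y_T   = sum_i mean_t(y_{i,t})       temporal mean of community biomass
    sig_T = sd_t( sum_i y_{i,t} )       temporal SD of community biomass
    S_com = Y_T / sig_T                 community stability (inverse CV)
    S_sp  = Y_T / sum_i sd_t(y_{i,t})   species stability
    phi   = sum_i sd_t(y_{i,t}) / sig_T species asynchrony

so that S_com = S_sp * phi identically, and phi >= 1 because the SD of a
sum never exceeds the sum of SDs (equality at perfect synchrony).  SDs are
sample SDs (n-1 denominator) by default; the identity holds for either
denominator but reported magnitudes differ, so the choice is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from befstab.data_model import Dataset


@dataclass
class StabilityResult:
    plot_id: str
    mean_total: float  # Y_T
    sd_total: float  # sig_T
    community_stability: float  # S_com
    species_stability: float  # S_sp
    asynchrony: float  # phi
    n_years: int
    n_species: int
    finite: bool  # False when sig_T == 0 (flagged, excluded downstream)

    def as_row(self) -> dict:
        return dict(self.__dict__)


def stability_partition(
    matrix: pd.DataFrame | np.ndarray,
    plot_id: str = "",
    ddof: int = 1,
) -> StabilityResult:
    """Partition stability for one plot's species-by-year biomass matrix.

    ``matrix`` has one row per year and one column per species (a plain
    array is accepted).  Two years are the algebraic minimum for a sample
    SD; :func:`partition_all_plots` applies the stricter 3-year floor used
    for whole-dataset runs.  A constant community
    total gives infinite stability: the result is returned flagged
    non-finite rather than raising, so callers can count and drop it.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    n_years, n_species = arr.shape
    if n_years < 2:
        raise ValueError(f"stability needs >= 2 years, got {n_years}")
    if (arr < 0).any():
        raise ValueError("negative biomass in stability matrix")
    totals = arr.sum(axis=1)
    y_t = float(arr.mean(axis=0).sum())
    sd_t = float(totals.std(ddof=ddof))
    sd_i = arr.std(axis=0, ddof=ddof)
    sum_sd = float(sd_i.sum())
    # a CV at machine precision is not a measurable quantity: treat a total
    # SD below ~1e-12 of the mean like the exactly-constant case
    if sd_t <= 1e-12 * max(y_t, 1.0):
        return StabilityResult(
            plot_id, y_t, sd_t, np.inf, np.inf if sum_sd == 0 else y_t / sum_sd,
            np.nan, n_years, n_species, False,
        )
    assert sum_sd > 0, "species SDs cannot all vanish when the total varies"
    s_com = y_t / sd_t
    s_sp = y_t / sum_sd
    phi = sum_sd / sd_t
    assert phi >= 1.0 - 1e-12, "sum of SDs must dominate SD of sum"
    assert abs(s_com - s_sp * phi) <= 1e-12 * abs(s_com), "multiplicative identity"
    return StabilityResult(plot_id, y_t, sd_t, s_com, s_sp, phi, n_years, n_species, True)


def plot_matrix(ds: Dataset, plot_id: str, exclude_imputed: bool = False) -> pd.DataFrame:
    """Year-by-species biomass matrix for one plot.

    Planted species missing in a year contribute 0 that year.  With
    ``exclude_imputed`` any year containing imputed biomass is dropped
    (sensitivity variant); by default imputed values are used as data.
    """
    obs = ds.observations
    sub = obs[(obs["plot_id"] == plot_id) & obs["biomass"].notna()]
    if exclude_imputed and "imputed" in sub.columns:
        bad_years = set(sub.loc[sub["imputed"].astype(bool), "year"])
        sub = sub[~sub["year"].isin(bad_years)]
    planted = sorted(ds.planted[plot_id])
    years = sorted(sub["year"].unique())
    return (
        sub.pivot_table(index="year", columns="species_id", values="biomass", aggfunc="sum")
        .reindex(index=years, columns=planted)
        .fillna(0.0)
    )


def partition_all_plots(
    ds: Dataset, ddof: int = 1, exclude_imputed: bool = False
) -> pd.DataFrame:
    """Stability partition for every plot; non-finite plots flagged.

    ``attrs['n_nonfinite']`` counts plots with a constant community total.
    """
    rows = []
    for plot_id in ds.plots["plot_id"]:
        mat = plot_matrix(ds, plot_id, exclude_imputed=exclude_imputed)
        if len(mat) < 3:
            continue
        rows.append(stability_partition(mat, plot_id=plot_id, ddof=ddof).as_row())
    out = pd.DataFrame(rows)
    out.attrs["n_nonfinite"] = int((~out["finite"]).sum()) if len(out) else 0
    return out
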