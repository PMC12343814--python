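"""Cover-based imputation of species-level biomass for unsorted plot-years.

Some plot-years were weighed only as a community total ("unsorted").  The
fill procedure has four steps: (1) for plots with both sorted biomass and
cover, fit per-species no-intercept linear models of plot-mean biomass on
plot-mean cover; (2) predict biomass from the observed cover of each species
in the unsorted plot-year; (3) normalise predictions to proportions; (4)
multiply by the observed community total.  Imputed biomasses therefore sum
to the observed total exactly, and rescaling all slopes by a common factor
leaves the result unchanged.

The no-intercept goodness of fit is the uncentred R^2,
``1 - sum((y - yhat)^2) / sum(y^2)``, the standard choice for
through-origin regressions (it can be negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from befstab.data_model import Dataset


class DegeneratePredictorError(ValueError):
    """All cover values are zero while biomass is not: slope undefined."""


class UnresolvableImputationError(ValueError):
    """Predicted community biomass is zero while the observed total is positive."""


@dataclass
class CoverBiomassModel:
    species_id: str
    slope: float  # g m^-2 per percent cover
    n_plots: int
    r_squared: float  # uncentred; <= 1, may be negative


def fit_cover_models(ds: Dataset) -> dict[str, CoverBiomassModel]:
    """Fit one through-origin cover->biomass model per species.

    Predictor/response pairs are per-plot means over the plot's sorted
    years (cover and biomass both present).  Species with no sorted record
    anywhere are simply absent from the result; imputation falls back to
    cover shares for them.
    """
    obs = ds.observations
    usable = obs[obs["sorted"].astype(bool) & obs["biomass"].notna() & obs["cover"].notna()]
    models: dict[str, CoverBiomassModel] = {}
    for sid, grp in usable.groupby("species_id"):
        per_plot = grp.groupby("plot_id")[["cover", "biomass"]].mean()
        x = per_plot["cover"].to_numpy()
        y = per_plot["biomass"].to_numpy()
        sxx = float(np.sum(x * x))
        if sxx == 0.0:
            if np.any(y > 0):
                raise DegeneratePredictorError(
                    f"species {sid}: all mean covers are zero (degenerate predictor)"
                )
            continue
        slope = float(np.sum(x * y) / sxx)
        resid = y - slope * x
        syy = float(np.sum(y * y))
        r2 = 1.0 - float(np.sum(resid**2)) / syy if syy > 0 else np.nan
        models[str(sid)] = CoverBiomassModel(str(sid), slope, len(per_plot), r2)
    return models


def impute_plot_year(
    models: dict[str, CoverBiomassModel],
    cover: dict[str, float],
    total_biomass: float,
) -> tuple[dict[str, float], list[str]]:
    """Allocate an observed community total across species by predicted share.

    Returns (imputed biomass by species, list of species that used the
    cover-share fallback because no cover model exists for them).  Raises
    :class:`UnresolvableImputationError` when every prediction is zero but
    the total is positive.
    """
    species = sorted(cover)
    if total_biomass == 0.0:
        return {s: 0.0 for s in species}, []
    have = [s for s in species if s in models]
    fallback = [s for s in species if s not in models]
    # fallback slope: mean of available slopes, or 1 (pure cover share)
    fb_slope = float(np.mean([models[s].slope for s in have])) if have else 1.0
    predicted = {
        s: (models[s].slope if s in models else fb_slope) * max(cover[s], 0.0) for s in species
    }
    denom = sum(predicted.values())
    if denom <= 0.0:
        raise UnresolvableImputationError(
            f"predicted community biomass is zero but observed total is {total_biomass}"
        )
    imputed = {s: predicted[s] / denom * total_biomass for s in species}
    return imputed, fallback


@dataclass
class ImputationReport:
    n_unsorted_plot_years: int
    n_imputed_plot_years: int
    n_unresolvable_plot_years: int
    n_imputed_records: int
    imputed_fraction_of_records: float
    fallback_species: list
    mode: str


def impute_dataset(
    ds: Dataset,
    models: dict[str, CoverBiomassModel] | None = None,
    mode: str = "on",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Dataset, ImputationReport]:
    """Fill unsorted plot-years; returns a completed dataset plus a report.

    ``mode``:
      * ``"on"`` — standard four-step imputation;
      * ``"off"`` — sensitivity variant dropping unsorted plot-years
        entirely (observations and totals);
      * ``"noisy"`` — sensitivity variant multiplying each prediction by
        mean-one lognormal noise of SD ``noise_sd`` before renormalising.

    Unresolvable plot-years (zero predicted mass against a positive total)
    are dropped and counted.  The output gains an ``imputed`` bool column.
    """
    if mode not in {"on", "off", "noisy"}:
        raise ValueError(f"unknown imputation mode '{mode}'")
    out = ds.copy()
    obs = out.observations
    if "imputed" not in obs.columns:
        obs["imputed"] = False
    unsorted = ds.unsorted_plot_years()
    keys = list(unsorted.itertuples(index=False, name=None))

    if mode == "off":
        drop = set(keys)
        mask_obs = [
            (p, y) in drop for p, y in zip(obs["plot_id"], obs["year"])
        ]
        out.observations = obs[~np.array(mask_obs, dtype=bool)].reset_index(drop=True)
        tot = out.totals
        mask_tot = [(p, y) in drop for p, y in zip(tot["plot_id"], tot["year"])]
        out.totals = tot[~np.array(mask_tot, dtype=bool)].reset_index(drop=True)
        rep = ImputationReport(len(keys), 0, 0, 0, 0.0, [], mode)
        return out, rep

    if models is None:
        models = fit_cover_models(ds)
    rng = np.random.default_rng(seed)
    totals_map = {
        (r.plot_id, r.year): r.total_biomass for r in ds.totals.itertuples()
    }
    obs = obs.set_index(["plot_id", "year", "species_id"]).sort_index()
    n_imputed_records = 0
    unresolvable = []
    fallback_all: set[str] = set()
    for plot_id, year in keys:
        rows = obs.loc[(plot_id, year)]
        cover = rows["cover"].fillna(0.0).to_dict()
        total = totals_map.get((plot_id, year))
        if total is None:
            unresolvable.append((plot_id, year))
            continue
        if mode == "noisy" and noise_sd > 0:
            # multiplying predictions by mean-one noise and renormalising is
            # equivalent to perturbing the per-species predictions directly
            jitter = np.exp(noise_sd * rng.standard_normal(len(cover)) - 0.5 * noise_sd**2)
        try:
            imputed, fb = impute_plot_year(models, cover, float(total))
        except UnresolvableImputationError:
            unresolvable.append((plot_id, year))
            continue
        if mode == "noisy" and noise_sd > 0:
            sids = sorted(imputed)
            vals = np.array([imputed[s] for s in sids]) * jitter[: len(sids)]
            if vals.sum() > 0:
                vals = vals / vals.sum() * float(total)
            imputed = dict(zip(sids, vals))
        fallback_all.update(fb)
        for sid, val in imputed.items():
            obs.loc[(plot_id, year, sid), "biomass"] = val
            obs.loc[(plot_id, year, sid), "imputed"] = True
            n_imputed_records += 1
    out.observations = obs.reset_index()
    if unresolvable:
        drop = set(unresolvable)
        o = out.observations
        mask = np.array([(p, y) in drop for p, y in zip(o["plot_id"], o["year"])])
        out.observations = o[~mask].reset_index(drop=True)
        t = out.totals
        mask = np.array([(p, y) in drop for p, y in zip(t["plot_id"], t["year"])])
        out.totals = t[~mask].reset_index(drop=True)
    rep = ImputationReport(
        n_unsorted_plot_years=len(keys),
        n_imputed_plot_years=len(keys) - len(unresolvable),
        n_unresolvable_plot_years=len(unresolvable),
        n_imputed_records=n_imputed_records,
        imputed_fraction_of_records=(
            n_imputed_records / len(out.observations) if len(out.observations) else 0.0
        ),
        fallback_species=sorted(fallback_all),
        mode=mode,
    )
    return out, rep


def evaluate_predictability(
    ds: Dataset, models: dict[str, CoverBiomassModel] | None = None
) -> pd.DataFrame:
    """Per-species R^2 of weighted-predicted vs measured biomass.

    For every *sorted* plot-year the four-step procedure is replayed as if
    the plot-year were unsorted (predict from cover, renormalise to the
    observed total); the measured species biomass is then regressed on the
    weighted prediction and the squared Pearson correlation reported per
    species.  Species with fewer than two usable points or degenerate
    variance get a missing R^2.
    """
    if models is None:
        models = fit_cover_models(ds)
    obs = ds.observations
    sorted_obs = obs[obs["sorted"].astype(bool) & obs["biomass"].notna()]
    totals_map = {(r.plot_id, r.year): r.total_biomass for r in ds.totals.itertuples()}
    pairs: dict[str, list[tuple[float, float]]] = {}
    for (plot_id, year), grp in sorted_obs.groupby(["plot_id", "year"]):
        cover = grp.set_index("species_id")["cover"].fillna(0.0).to_dict()
        total = totals_map.get((plot_id, year))
        if total is None:
            continue
        try:
            imputed, _ = impute_plot_year(models, cover, float(total))
        except UnresolvableImputationError:
            continue
        for sid, measured in zip(grp["species_id"], grp["biomass"]):
            pairs.setdefault(str(sid), []).append((imputed[str(sid)], float(measured)))
    rows = []
    for sid in sorted(pairs):
        arr = np.array(pairs[sid])
        if len(arr) < 2 or arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1] ** 2)
        rows.append({"species_id": sid, "r_squared": r2, "n_plot_years": len(arr)})
    table = pd.DataFrame(rows)
    table.attrs["n_reliable"] = int((table["r_squared"] > 0.5).sum()) if len(table) else 0
    return table
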