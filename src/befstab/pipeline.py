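"""End-to-end orchestration: raw tables -> partitions -> inference -> SEM.

The canonical run is: validate, drop flagged plots, fit cover models and
gap-fill unsorted plot-years, compute the functioning (dY/CE/SE) and
stability (S_com = S_sp * phi) partitions per plot, assemble the per-plot
master table, fit the bivariate mixed-model suite, and fit the multi-group
piecewise SEM across the four treatment combinations
(ambient / eCO2 / N / eCO2+N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from befstab import gapfill
from befstab.data_model import Dataset, filter_analysis_plots
from befstab.diversity_effects import partition_all_mixtures
from befstab.sem import SemFit, default_sem_model, multigroup
from befstab.stability_partition import partition_all_plots
from befstab.suite import run_bivariate_suite, tidy_wald
from befstab.synthetic_data import SimulationConfig, simulate_dataset


def treatment_label(co2: str, nitrogen: str) -> str:
    if co2 == "elevated" and nitrogen == "enriched":
        return "eCO2+N"
    if co2 == "elevated":
        return "eCO2"
    if nitrogen == "enriched":
        return "N"
    return "ambient"


def build_master_table(
    ds: Dataset,
    fn_table: pd.DataFrame,
    stab_table: pd.DataFrame,
) -> pd.DataFrame:
    """One row per plot: design factors, partitions, transformed SEM columns."""
    meta = ds.plots[["plot_id", "ring_id", "co2", "nitrogen", "planted_richness"]].rename(
        columns={"planted_richness": "richness"}
    )
    meta["treatment"] = [
        treatment_label(c, n) for c, n in zip(meta["co2"], meta["nitrogen"])
    ]
    stab = stab_table.rename(
        columns={
            "mean_total": "productivity",
            "community_stability": "community_stability",
            "species_stability": "species_stability",
            "asynchrony": "asynchrony",
        }
    )[
        [
            "plot_id",
            "productivity",
            "community_stability",
            "species_stability",
            "asynchrony",
            "finite",
        ]
    ]
    fn = fn_table[["plot_id", "delta_y", "ce", "se"]] if len(fn_table) else pd.DataFrame(
        columns=["plot_id", "delta_y", "ce", "se"]
    )
    master = meta.merge(stab, on="plot_id", how="left").merge(fn, on="plot_id", how="left")
    master.loc[~master["finite"].fillna(False).astype(bool), ["community_stability", "asynchrony"]] = np.nan
    master["log_sr"] = np.log(master["richness"].astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        master["productivity_log"] = np.log(master["productivity"])
        master["community_stability_log"] = np.log(master["community_stability"])
        master["species_stability_log"] = np.log(master["species_stability"])
        master["asynchrony_log"] = np.log(master["asynchrony"])
    return master


@dataclass
class PipelineResult:
    dataset: Dataset
    validation: object
    cover_models: dict
    imputation: gapfill.ImputationReport
    predictability: pd.DataFrame
    fn_table: pd.DataFrame
    stab_table: pd.DataFrame
    master: pd.DataFrame
    suite: dict
    wald_tables: pd.DataFrame
    sem_fit: SemFit | None
    logs: list = field(default_factory=list)


def run_pipeline(
    ds: Dataset,
    imputation: str = "on",
    imputation_noise_sd: float = 0.0,
    variance: str = "homoscedastic",
    wald_mode: str = "wald",
    sem_alpha: float = 0.05,
    run_sem: bool = True,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on a validated dataset."""
    logs: list[str] = []
    report = ds.validate()
    analysis = filter_analysis_plots(ds, log=logs.append)

    models = gapfill.fit_cover_models(analysis)
    filled, imp_report = gapfill.impute_dataset(
        analysis, models, mode=imputation, noise_sd=imputation_noise_sd, seed=seed
    )
    predictability = gapfill.evaluate_predictability(analysis, models)

    fn_table = partition_all_mixtures(filled)
    stab_table = partition_all_plots(filled)
    if stab_table.attrs.get("n_nonfinite"):
        logs.append(f"{stab_table.attrs['n_nonfinite']} plot(s) with non-finite stability dropped")

    master = build_master_table(filled, fn_table, stab_table)
    suite = run_bivariate_suite(master, variance=variance, mode=wald_mode)
    wald_tables = tidy_wald(suite)

    sem_fit = None
    if run_sem:
        sem_cols = default_sem_model().nodes + ["ring_id", "treatment"]
        sem_data = master.dropna(subset=default_sem_model().nodes)[sem_cols]
        sem_fit = multigroup(default_sem_model(), sem_data, "treatment", alpha=sem_alpha)
    return PipelineResult(
        dataset=filled,
        validation=report,
        cover_models=models,
        imputation=imp_report,
        predictability=predictability,
        fn_table=fn_table,
        stab_table=stab_table,
        master=master,
        suite=suite,
        wald_tables=wald_tables,
        sem_fit=sem_fit,
        logs=logs,
    )


def run_synthetic_pipeline(
    config: SimulationConfig | None = None, **kwargs
) -> tuple[PipelineResult, object]:
    """Simulate a dataset under ``config`` and run the full analysis on it."""
    config = config or SimulationConfig()
    ds, truth = simulate_dataset(config)
    result = run_pipeline(ds, seed=config.seed, **kwargs)
    return result, truth
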