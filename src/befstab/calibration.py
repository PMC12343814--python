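"""Seeded Monte-Carlo calibration studies for the inference machinery.

These functions quantify, on synthetic data whose ground truth is known by
construction, the operating characteristics a user should expect from the
pipeline: power to recover the richness-overyielding signal, type-I error
of the type-III tests under a null community, asynchrony response to the
generator's synchrony mixing weight, the multi-group SEM's path decisions,
and the calibration of the d-separation global test under a true model.

Problem sizes are chosen to finish in minutes on one core; each function
takes a base seed and is fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from befstab.diversity_effects import partition_all_mixtures
from befstab.lmm import ModelSpec, fit_lmm, type3_wald
from befstab.sem import SemModel, fit_psem, multigroup
from befstab.stability_partition import partition_all_plots
from befstab.synthetic_data import SimulationConfig, simulate_dataset

_FLAT = {g: 1.0 for g in ("C3 grass", "C4 grass", "legume", "forb")}

TREATMENT_RHS = "np.log(richness) * C(co2, Sum) * C(nitrogen, Sum)"


def _null_config(seed: int, **kw) -> SimulationConfig:
    base = dict(
        replicates={1: 16, 4: 10, 9: 10, 16: 10},
        n_years=5,
        ce_base=0.0,
        ce_log_richness_slope=0.0,
        delta_se=0.0,
        co2_multiplier=dict(_FLAT),
        n_multiplier=dict(_FLAT),
        f_unsorted=0.0,
        n_excluded_precip=0,
        n_excluded_warming=0,
        seed=seed,
    )
    base.update(kw)
    return SimulationConfig(**base)


def ce_richness_power(n_reps: int = 100, seed: int = 0) -> float:
    """Fraction of replicates recovering the positive richness-CE slope.

    Each replicate simulates a community whose overyield coefficient grows
    with log richness (the generator default), runs the additive partition,
    and tests the richness term on CE in the treatment model.  Success =
    P < 0.05 with a positive coefficient.
    """
    hits = 0
    for rep in range(n_reps):
        cfg = _null_config(
            seed + rep, ce_log_richness_slope=0.25,
            replicates={1: 16, 4: 5, 9: 4, 16: 3}, n_years=8,
        )
        ds, _ = simulate_dataset(cfg)
        fn = partition_all_mixtures(ds)
        data = fn.merge(
            ds.plots[["plot_id", "ring_id", "co2", "nitrogen"]], on="plot_id"
        )
        fit = fit_lmm(ModelSpec(f"ce ~ {TREATMENT_RHS}", groups=["ring_id"]), data)
        tab = type3_wald(fit)
        if tab.loc["np.log(richness)", "p"] < 0.05 and fit.params["np.log(richness)"] > 0:
            hits += 1
    return hits / n_reps


def type1_error_rate(n_reps: int = 400, seed: int = 0) -> float:
    """Rejection rate of the three-way interaction on null communities.

    The null generator removes every systematic effect AND satisfies the
    fitted model's assumptions: equal species means (no composition lottery
    at low richness) and independent species shocks, so the log community
    mean has variance proportional to 1/N — exactly the exponential
    variance law in log richness that the model's ``varExp`` structure
    absorbs.  The fit uses that structure; the richness x CO2 x N Wald
    P value should then be uniform and the rejection rate nominal.  The
    Wald test is asymptotic, so calibration runs at study scale
    (~288 plots).
    """
    hits = 0
    for rep in range(n_reps):
        cfg = _null_config(
            seed + 100_000 + rep,
            replicates={1: 24, 4: 16, 9: 16, 16: 16},
            mu=np.full(16, 120.0),
            rho_sync=0.0,
        )
        ds, _ = simulate_dataset(cfg)
        prod = (
            ds.totals.groupby("plot_id")["total_biomass"].mean().rename("productivity")
        )
        data = ds.plots.merge(prod, on="plot_id").rename(
            columns={"planted_richness": "richness"}
        )
        data["log_sr"] = np.log(data["richness"])
        fit = fit_lmm(
            ModelSpec(
                f"np.log(productivity) ~ {TREATMENT_RHS}",
                groups=["ring_id"],
                variance="exp",
                variance_covariate="log_sr",
            ),
            data,
        )
        p = type3_wald(fit).loc["np.log(richness):C(co2, Sum):C(nitrogen, Sum)", "p"]
        if p < 0.05:
            hits += 1
    return hits / n_reps


def asynchrony_by_synchrony_weight(
    rhos=(0.0, 0.5, 1.0), seed: int = 0
) -> pd.Series:
    """Mean mixture asynchrony at each shared-shock mixing weight (no noise)."""
    out = {}
    for rho in rhos:
        cfg = _null_config(
            seed, rho_sync=float(rho), sigma_obs=0.0, sigma_cover=0.0, n_years=12,
            lambda_loading=0.4,
        )
        ds, _ = simulate_dataset(cfg)
        tab = partition_all_plots(ds)
        out[float(rho)] = float(tab.loc[tab["n_species"] > 1, "asynchrony"].mean())
    return pd.Series(out)


def _two_group_frame(rng, slope_a: float, slope_b: float, n_per: int, noise: float):
    x = rng.normal(0, 1, 2 * n_per)
    grp = np.repeat(["A", "B"], n_per)
    slope = np.where(grp == "A", slope_a, slope_b)
    y = slope * x + rng.normal(0, noise, 2 * n_per)
    return pd.DataFrame({"x": x, "y": y, "grp": grp})


def multigroup_decision_rates(n_reps: int = 100, seed: int = 0) -> dict:
    """Specificity and sensitivity of the constrained/unconstrained decision.

    Specificity: identical slopes in two groups -> path kept constrained.
    Sensitivity: slopes +1 vs -1 with small noise -> path freed.
    """
    model = SemModel(nodes=["x", "y"], edges=[("x", "y")])
    rng = np.random.default_rng(seed)
    constrained_ok = freed_ok = 0
    for _ in range(n_reps):
        same = _two_group_frame(rng, 1.0, 1.0, n_per=120, noise=1.0)
        fit = multigroup(model, same, "grp")
        if fit.paths["constrained"].all():
            constrained_ok += 1
        diff = _two_group_frame(rng, 1.0, -1.0, n_per=120, noise=0.3)
        fit = multigroup(model, diff, "grp")
        if not fit.paths["constrained"].any():
            freed_ok += 1
    return {"specificity": constrained_ok / n_reps, "sensitivity": freed_ok / n_reps}


def dsep_global_p_calibration(n_reps: int = 200, seed: int = 0, n: int = 200) -> float:
    """Rejection rate of Fisher's C when the fitted chain IS the generator.

    Data follow x -> y -> z exactly; the single claim (x independent of z
    given y) is true, so the global P should be uniform and the P < 0.05
    rate should match the nominal level.
    """
    model = SemModel(nodes=["x", "y", "z"], edges=[("x", "y"), ("y", "z")])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0, 1, n)
        z = y + rng.normal(0, 1, n)
        fit = fit_psem(model, pd.DataFrame({"x": x, "y": y, "z": z}))
        if fit.p_value < 0.05:
            hits += 1
    return hits / n_reps
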