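import numpy as np
import pandas as pd
import pytest

from befstab import gapfill
from befstab.data_model import Dataset
from befstab.synthetic_data import simulate_dataset

from conftest import make_config, toy_dataset


def dataset_from_pairs(pairs):
    """One species observed across plots with given (mean cover, mean biomass)."""
    species = pd.DataFrame({"species_id": ["spA"], "functional_group": ["forb"]})
    plots = pd.DataFrame(
        {
            "plot_id": [f"P{i}" for i in range(len(pairs))],
            "ring_id": 1,
            "co2": "ambient",
            "nitrogen": "ambient",
            "planted_richness": 1,
            "planted_species": "spA",
            "excluded": False,
            "exclusion_reason": pd.NA,
        }
    )
    obs = pd.DataFrame(
        [
            dict(plot_id=f"P{i}", year=2000, species_id="spA",
                 biomass=b, cover=c, sorted=True)
            for i, (c, b) in enumerate(pairs)
        ]
    )
    totals = obs.groupby(["plot_id", "year"], as_index=False)["biomass"].sum().rename(
        columns={"biomass": "total_biomass"}
    )
    return Dataset(species, plots, obs, totals)


def test_exact_proportionality_slope_and_r2():
    models = gapfill.fit_cover_models(dataset_from_pairs([(10, 20), (20, 40)]))
    m = models["spA"]
    assert m.slope == pytest.approx(2.0)
    assert m.r_squared == pytest.approx(1.0)
    assert m.n_plots == 2


def test_normal_equation_slope_hand_computed():
    # slope = (10*18 + 20*44) / (10^2 + 20^2) = 1060/500 = 2.12
    models = gapfill.fit_cover_models(dataset_from_pairs([(10, 18), (20, 44)]))
    assert models["spA"].slope == pytest.approx(2.12)
    assert models["spA"].r_squared < 1.0


def test_all_zero_cover_is_degenerate():
    with pytest.raises(gapfill.DegeneratePredictorError, match="degenerate"):
        gapfill.fit_cover_models(dataset_from_pairs([(0.0, 18), (0.0, 44)]))


def test_impute_single_species_gets_whole_total():
    models = {"spA": gapfill.CoverBiomassModel("spA", 3.0, 5, 0.9)}
    imputed, fb = gapfill.impute_plot_year(models, {"spA": 7.0}, 55.0)
    assert imputed == {"spA": pytest.approx(55.0)}
    assert fb == []


def test_impute_hand_computed_shares():
    models = {
        "A": gapfill.CoverBiomassModel("A", 2.0, 3, 0.9),
        "B": gapfill.CoverBiomassModel("B", 1.0, 3, 0.9),
    }
    imputed, _ = gapfill.impute_plot_year(models, {"A": 10.0, "B": 20.0}, 30.0)
    assert imputed["A"] == pytest.approx(15.0)
    assert imputed["B"] == pytest.approx(15.0)


def test_impute_zero_total_gives_zeros():
    models = {"A": gapfill.CoverBiomassModel("A", 2.0, 3, 0.9)}
    imputed, _ = gapfill.impute_plot_year(models, {"A": 10.0}, 0.0)
    assert imputed == {"A": 0.0}


def test_impute_zero_prediction_unresolvable():
    models = {"A": gapfill.CoverBiomassModel("A", 2.0, 3, 0.9)}
    with pytest.raises(gapfill.UnresolvableImputationError):
        gapfill.impute_plot_year(models, {"A": 0.0}, 30.0)


def test_scale_equivariance_of_imputation():
    rng = np.random.default_rng(0)
    for _ in range(50):
        slopes = rng.uniform(0.5, 5.0, 4)
        covers = rng.uniform(0.0, 50.0, 4)
        if covers.sum() == 0:
            continue
        total = rng.uniform(1.0, 500.0)
        models1 = {f"s{i}": gapfill.CoverBiomassModel(f"s{i}", s, 2, 0.9) for i, s in enumerate(slopes)}
        models2 = {f"s{i}": gapfill.CoverBiomassModel(f"s{i}", 7.3 * s, 2, 0.9) for i, s in enumerate(slopes)}
        cov = {f"s{i}": c for i, c in enumerate(covers)}
        a, _ = gapfill.impute_plot_year(models1, cov, total)
        b, _ = gapfill.impute_plot_year(models2, cov, total)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)
        assert sum(a.values()) == pytest.approx(total, rel=1e-9)


def test_mass_conservation_on_simulated_data():
    ds, _ = simulate_dataset(make_config(f_unsorted=0.25, seed=2))
    filled, report = gapfill.impute_dataset(ds)
    assert report.n_imputed_plot_years > 0
    obs = filled.observations
    imp_keys = obs.loc[obs["imputed"], ["plot_id", "year"]].drop_duplicates()
    sums = obs.groupby(["plot_id", "year"])["biomass"].sum()
    totals = filled.totals.set_index(["plot_id", "year"])["total_biomass"]
    for plot_id, year in imp_keys.itertuples(index=False):
        t = totals.loc[(plot_id, year)]
        assert abs(sums.loc[(plot_id, year)] - t) < 1e-9 * max(t, 1.0)


def test_exact_recovery_without_noise():
    """With exactly proportional cover and no noise, imputation returns the truth."""
    cfg = make_config(f_unsorted=0.3, sigma_obs=0.0, sigma_cover=0.0, seed=4)
    # keep covers far from the 100% ceiling so proportionality stays exact
    cfg.cover_slope = cfg.mu / 20.0
    ds, truth = simulate_dataset(cfg)
    filled, _ = gapfill.impute_dataset(ds)
    merged = filled.observations.merge(
        truth.expected, on=["plot_id", "year", "species_id"]
    )
    imp = merged[merged["imputed"]]
    assert len(imp) > 100
    assert np.allclose(imp["biomass"], imp["expected_biomass"], rtol=1e-8)


def test_imputation_off_drops_unsorted_plot_years():
    ds, _ = simulate_dataset(make_config(f_unsorted=0.25, seed=2))
    n_unsorted = len(ds.unsorted_plot_years())
    filled, report = gapfill.impute_dataset(ds, mode="off")
    assert report.mode == "off"
    assert len(filled.unsorted_plot_years()) == 0
    assert ds.totals.groupby(["plot_id", "year"]).ngroups - filled.totals.groupby(
        ["plot_id", "year"]
    ).ngroups == n_unsorted


def test_noisy_mode_still_conserves_mass():
    ds, _ = simulate_dataset(make_config(f_unsorted=0.25, seed=2))
    filled, _ = gapfill.impute_dataset(ds, mode="noisy", noise_sd=0.3, seed=9)
    obs = filled.observations
    imp_keys = obs.loc[obs["imputed"], ["plot_id", "year"]].drop_duplicates()
    sums = obs.groupby(["plot_id", "year"])["biomass"].sum()
    totals = filled.totals.set_index(["plot_id", "year"])["total_biomass"]
    for plot_id, year in imp_keys.head(50).itertuples(index=False):
        assert sums.loc[(plot_id, year)] == pytest.approx(totals.loc[(plot_id, year)])
    # and actually perturbs the allocation relative to the noise-free fill
    clean, _ = gapfill.impute_dataset(ds, mode="on")
    a = obs.sort_values(["plot_id", "year", "species_id"])["biomass"].to_numpy()
    b = clean.observations.sort_values(["plot_id", "year", "species_id"])["biomass"].to_numpy()
    assert not np.allclose(a[np.isfinite(a)], b[np.isfinite(b)])


def test_predictability_perfect_on_noise_free_cover():
    cfg = make_config(sigma_obs=0.0, sigma_cover=0.0, seed=3)
    ds, _ = simulate_dataset(cfg)
    table = gapfill.evaluate_predictability(ds)
    assert (table["r_squared"].dropna() > 0.999).all()


def test_predictability_isolates_noisy_species():
    """Cover noise on one species degrades chiefly that species' R^2.

    Because imputation renormalises predictions to the observed total, noise
    on one species leaks mildly into its plot-mates' weighted predictions;
    the clean species nevertheless stay far above the perturbed one.
    """
    mu = np.array([60.0, 90.0, 140.0, 220.0])
    cfg = make_config(
        replicates={1: 6, 4: 8}, n_species=4, sigma_obs=0.0, sigma_cover=0.0,
        mu=mu, cover_slope=mu / 20.0, seed=6,
    )
    ds, _ = simulate_dataset(cfg)
    rng = np.random.default_rng(0)
    noisy = ds.observations["species_id"] == "sp02"
    ds.observations.loc[noisy, "cover"] *= np.exp(1.2 * rng.standard_normal(noisy.sum()))
    table = gapfill.evaluate_predictability(ds).set_index("species_id")
    good = table.drop(index="sp02")["r_squared"]
    assert (good > 0.9).all() and len(good) == 3
    assert table.loc["sp02", "r_squared"] < 0.7


def test_predictability_single_plot_year_missing():
    ds = dataset_from_pairs([(10, 20)])
    table = gapfill.evaluate_predictability(ds)
    assert np.isnan(table.loc[0, "r_squared"])
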