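import numpy as np
import pandas as pd
import pytest

from befstab.lmm import (
    AliasedTermError,
    ModelSpec,
    fit_lmm,
    significance_band,
    type3_wald,
)


def simulate_grouped(
    seed=0, n_groups=6, per_group=40, slope=2.0, sd_group=0.5, sd_eps=1.0, x_max=2.0
):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per_group)
    x = rng.uniform(0, x_max, len(g))
    u = rng.normal(0, sd_group, n_groups)
    y = 1.0 + slope * x + u[g] + rng.normal(0, sd_eps, len(g))
    return pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})


def test_closed_form_ols_slope():
    # x=[0,1,2], y=[0,1,3] -> slope sum((x-xb)(y-yb))/sum((x-xb)^2) = 3/2
    data = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 3.0]})
    fit = fit_lmm(ModelSpec("y ~ x"), data)
    assert fit.params["x"] == pytest.approx(1.5)


def test_degenerate_random_effect_matches_ols():
    data = simulate_grouped(seed=1, sd_group=0.0)
    mixed = fit_lmm(ModelSpec("y ~ x", groups=["g"]), data)
    ols = fit_lmm(ModelSpec("y ~ x"), data)
    assert mixed.params["x"] == pytest.approx(ols.params["x"], rel=1e-3)
    assert mixed.params["Intercept"] == pytest.approx(ols.params["Intercept"], rel=1e-3)


def test_against_statsmodels_mixedlm():
    """Coefficients, loglik and variance ratio agree with an independent ML fit."""
    sm = pytest.importorskip("statsmodels.formula.api")
    data = simulate_grouped(seed=2, sd_group=0.8)
    ours = fit_lmm(ModelSpec("y ~ x", groups=["g"]), data)
    theirs = sm.mixedlm("y ~ x", data, groups=data["g"]).fit(reml=False)
    assert ours.params["x"] == pytest.approx(theirs.params["x"], rel=1e-4)
    assert ours.params["Intercept"] == pytest.approx(theirs.params["Intercept"], rel=1e-4)
    assert ours.loglik == pytest.approx(theirs.llf, abs=1e-3)
    # group variance ratio gamma^2 = tau^2 / sigma^2
    assert ours.variance_ratios["g"] * ours.sigma2 == pytest.approx(
        float(theirs.cov_re.iloc[0, 0]), rel=5e-2
    )


def test_monte_carlo_slope_recovery():
    """Slope estimate lands in [1.9, 2.1] in >= 95% of 200 replicates.

    The covariate spans [0, 8] so that the slope's sampling SD at
    6 x 40 observations (~0.025) makes the +-0.1 window a >3-sigma event.
    """
    hits = 0
    for rep in range(200):
        data = simulate_grouped(seed=1000 + rep, x_max=8.0)
        fit = fit_lmm(ModelSpec("y ~ x", groups=["g"]), data)
        if 1.9 <= fit.params["x"] <= 2.1:
            hits += 1
    assert hits >= 190


def test_wald_chi2_equals_z_squared_for_1df_terms():
    data = simulate_grouped(seed=3)
    fit = fit_lmm(ModelSpec("y ~ x", groups=["g"]), data)
    tab = type3_wald(fit)
    z = fit.params["x"] / np.sqrt(fit.cov_params.loc["x", "x"])
    assert tab.loc["x", "chi2"] == pytest.approx(z**2, rel=1e-10)
    assert tab.loc["x", "df"] == 1
    assert "Intercept" not in tab.index


def test_term_absent_from_table():
    data = simulate_grouped(seed=4)
    data["w"] = 1.0  # never enters the formula
    tab = type3_wald(fit_lmm(ModelSpec("y ~ x", groups=["g"]), data))
    assert list(tab.index) == ["x"]


def test_type3_invariant_to_term_order_on_balanced_design():
    rng = np.random.default_rng(5)
    a = np.repeat(["lo", "hi"], 40)
    b = np.tile(np.repeat(["c", "t"], 20), 2)
    y = rng.normal(0, 1, 80) + (a == "hi") * 0.5 + (b == "t") * 0.3
    data = pd.DataFrame({"y": y, "a": a, "b": b})
    t1 = type3_wald(fit_lmm(ModelSpec("y ~ C(a, Sum) * C(b, Sum)"), data))
    t2 = type3_wald(fit_lmm(ModelSpec("y ~ C(b, Sum) * C(a, Sum)"), data))
    assert t1.loc["C(a, Sum)", "chi2"] == pytest.approx(t2.loc["C(a, Sum)", "chi2"], rel=1e-8)
    assert t1.loc["C(b, Sum)", "chi2"] == pytest.approx(t2.loc["C(b, Sum)", "chi2"], rel=1e-8)
    assert t1.loc["C(a, Sum):C(b, Sum)", "chi2"] == pytest.approx(
        t2.loc["C(b, Sum):C(a, Sum)", "chi2"], rel=1e-8
    )


def test_wald_invariant_to_affine_rescaling():
    data = simulate_grouped(seed=6)
    t1 = type3_wald(fit_lmm(ModelSpec("y ~ x", groups=["g"]), data))
    data2 = data.assign(x=data["x"] * 37.0 + 4.0)
    t2 = type3_wald(fit_lmm(ModelSpec("y ~ x", groups=["g"]), data2))
    assert t1.loc["x", "chi2"] == pytest.approx(t2.loc["x", "chi2"], rel=1e-8)


def test_exponential_variance_nests_homoscedastic():
    data = simulate_grouped(seed=7)
    homo = fit_lmm(ModelSpec("y ~ x", groups=["g"]), data)
    hetero = fit_lmm(ModelSpec("y ~ x", groups=["g"], variance="exp"), data)
    assert hetero.loglik >= homo.loglik - 1e-6


def test_exponential_variance_detects_heteroscedasticity():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 2, 400)
    y = 1 + 2 * x + rng.normal(0, 1, 400) * np.exp(0.8 * (x - 1))
    data = pd.DataFrame({"y": y, "x": x, "v": x})
    hetero = fit_lmm(ModelSpec("y ~ x", variance="exp", variance_covariate="v"), data)
    homo = fit_lmm(ModelSpec("y ~ x"), data)
    assert hetero.delta > 0.2
    assert hetero.loglik > homo.loglik + 5


def test_aliased_design_is_reported():
    data = simulate_grouped(seed=9)
    data["x2"] = 2.0 * data["x"]
    with pytest.raises(AliasedTermError, match="aliased"):
        fit_lmm(ModelSpec("y ~ x + x2", groups=["g"]), data)


def test_lr_mode_tracks_wald_for_moderate_effects():
    # the two statistics agree to first order near the null, not for huge effects
    data = simulate_grouped(seed=10, per_group=100, slope=0.2)
    fit = fit_lmm(ModelSpec("y ~ x", groups=["g"]), data)
    wald = type3_wald(fit, mode="wald").loc["x", "chi2"]
    lr = type3_wald(fit, mode="lr").loc["x", "chi2"]
    assert lr == pytest.approx(wald, rel=0.15, abs=0.2)


def test_nonfinite_rows_dropped_with_count():
    data = simulate_grouped(seed=11)
    data.loc[:4, "y"] = np.nan
    data.loc[5, "y"] = -np.inf
    fit = fit_lmm(ModelSpec("y ~ x", groups=["g"]), data)
    assert fit.n_dropped == 6
    assert fit.n_obs == len(data) - 6


def test_significance_bands():
    assert significance_band(0.0005) == "***"
    assert significance_band(0.005) == "**"
    assert significance_band(0.03) == "*"
    assert significance_band(0.07) == "."
    assert significance_band(0.5) == ""
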