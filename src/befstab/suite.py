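"""The bivariate mixed-model suite over the per-plot summary table.

Six treatment models (one per response: mean community productivity,
community stability, complementarity effect, selection effect, species
asynchrony, species stability) regress each response on
log(planted richness) x CO2 x N with ring random intercepts, and four link
models regress asynchrony / species stability on CE / SE x CO2 x N with
richness-within-ring random intercepts.  Stability, asynchrony and richness
enter on the natural-log scale; CE and SE, which take both signs, are never
log-transformed.  Every model is summarised by a type-III chi-square table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from befstab.lmm import LmmFit, ModelSpec, fit_lmm, type3_wald

TREATMENT_RHS = "np.log(richness) * C(co2, Sum) * C(nitrogen, Sum)"

#: response column -> transform for the six treatment models
TREATMENT_RESPONSES = {
    "productivity": "np.log(productivity)",
    "community_stability": "np.log(community_stability)",
    "ce": "ce",
    "se": "se",
    "asynchrony": "np.log(asynchrony)",
    "species_stability": "np.log(species_stability)",
}

#: (response transform, mechanism predictor) for the four link models
LINK_MODELS = {
    "asynchrony~ce": ("np.log(asynchrony)", "ce"),
    "asynchrony~se": ("np.log(asynchrony)", "se"),
    "species_stability~ce": ("np.log(species_stability)", "ce"),
    "species_stability~se": ("np.log(species_stability)", "se"),
}


def prepare_master(master: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns; drop rows with non-finite community stability."""
    out = master.copy()
    out["ring_richness"] = (
        out["ring_id"].astype(str) + "/" + out["richness"].astype(str)
    )
    for col in ("community_stability", "species_stability", "asynchrony"):
        if col in out.columns:
            out.loc[~np.isfinite(out[col].astype(float)), col] = np.nan
    return out


def run_bivariate_suite(
    master: pd.DataFrame,
    variance: str = "homoscedastic",
    mode: str = "wald",
) -> dict:
    """Fit all ten models; returns ``{name: {"fit": LmmFit, "wald": table}}``.

    ``variance="exp"`` engages the exponential variance structure in every
    model (covariate = fitted values); ``mode`` selects Wald or LR
    chi-squares for the type-III tables.
    """
    data = prepare_master(master)
    results: dict[str, dict] = {}
    for name, lhs in TREATMENT_RESPONSES.items():
        spec = ModelSpec(f"{lhs} ~ {TREATMENT_RHS}", groups=["ring_id"], variance=variance)
        fit = fit_lmm(spec, data)
        results[name] = {"fit": fit, "wald": type3_wald(fit, mode=mode)}
    for name, (lhs, mech) in LINK_MODELS.items():
        spec = ModelSpec(
            f"{lhs} ~ {mech} * C(co2, Sum) * C(nitrogen, Sum)",
            groups=["ring_id", "ring_richness"],
            variance=variance,
        )
        fit = fit_lmm(spec, data)
        results[name] = {"fit": fit, "wald": type3_wald(fit, mode=mode)}
    return results


def tidy_wald(results: dict) -> pd.DataFrame:
    """Stack every model's type-III table into one long dataframe."""
    frames = []
    for name, res in results.items():
        t = res["wald"].reset_index()
        t.insert(0, "model", name)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
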