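"""Gaussian linear mixed models for split-plot inference.

Fits random-intercept models by direct maximum likelihood on the marginal
covariance

    V = sigma^2 * ( D(delta) + sum_k gamma_k^2 Z_k Z_k' )

where Z_k are indicator matrices of the grouping factors (e.g. ring, or
richness-within-ring), gamma_k^2 are variance ratios, and D is either the
identity (homoscedastic) or ``diag(exp(2 delta v_i))`` — an exponential
variance function of a covariate v (by default the OLS fitted values),
mirroring the nlme ``varExp`` structure.  The error scale sigma^2 and the
fixed effects are profiled out, so the optimiser only searches the one-to-
three remaining variance parameters.

Type-III tests require estimable marginal hypotheses: write categorical
fixed effects with sum-to-zero contrasts, e.g. ``C(co2, Sum)`` in the patsy
formula.  :func:`type3_wald` then tests each term's coefficients jointly
(Wald chi-square, the car::Anova-style statistic); ``mode="lr"`` refits
without the term's columns and uses the likelihood-ratio chi-square
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrices
from scipy import linalg, optimize, stats


class SingularFitError(RuntimeError):
    pass


class AliasedTermError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Declarative model description.

    formula : patsy formula, response on the left (transforms inline, e.g.
        ``np.log(s_com) ~ np.log(richness) * C(co2, Sum) * C(nitrogen, Sum)``).
    groups : grouping column names, one random intercept per entry; nested
        structures are expressed by a combined column (e.g. ring then
        ring-by-richness).  Empty list = no random effects.
    variance : ``"homoscedastic"`` or ``"exp"`` (exponential-of-covariate).
    variance_covariate : column driving the exponential variance; ``None``
        uses OLS fitted values.
    """

    formula: str
    groups: list = field(default_factory=list)
    variance: str = "homoscedastic"
    variance_covariate: str | None = None


@dataclass
class LmmFit:
    spec: ModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    variance_ratios: dict  # group name -> gamma^2 (var ratio to sigma^2)
    delta: float  # exponential variance coefficient (0 if homoscedastic)
    loglik: float
    n_obs: int
    n_dropped: int
    term_slices: dict  # term name -> column index array
    k_params: int  # fixed coefficients + variance parameters (incl. sigma^2)
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _Zs: list = field(repr=False, default=None)
    _v: np.ndarray = field(repr=False, default=None)

    @property
    def coef_names(self):
        return list(self.params.index)

    def wald_z_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        z = self.params.to_numpy() / se
        return pd.DataFrame(
            {"coef": self.params, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))}
        )


def _indicator(col: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(col, sort=True)
    if (codes < 0).any():
        raise ValueError("missing values in grouping column")
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _profiled_nll(theta, y, X, Zs, v):
    """Negative profiled ML log-likelihood at variance parameters theta."""
    if np.any(np.abs(theta) > 6.0):
        return np.inf, None  # variance ratios beyond e^12 are numerical poison
    n = len(y)
    n_g = len(Zs)
    d = np.exp(2.0 * theta[n_g] * v) if v is not None else np.ones(n)
    V0 = np.diag(d)
    for k, Z in enumerate(Zs):
        gamma2 = np.exp(2.0 * theta[k])
        V0 += gamma2 * (Z @ Z.T)
    try:
        c, low = linalg.cho_factor(V0, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Xw = linalg.cho_solve((c, low), X, check_finite=False)
    yw = linalg.cho_solve((c, low), y, check_finite=False)
    XtVX = X.T @ Xw
    XtVy = X.T @ yw
    try:
        beta = linalg.solve(XtVX, XtVy, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf, None
    r = y - X @ beta
    rw = linalg.cho_solve((c, low), r, check_finite=False)
    sigma2 = float(r @ rw) / n
    if sigma2 <= 0:
        return np.inf, None
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return -ll, (beta, sigma2, XtVX, c, low)


def _fit_core(y, X, Zs, v):
    """Optimise variance parameters; return estimates and ML quantities."""
    n_var = len(Zs) + (1 if v is not None else 0)
    if n_var == 0:
        nll, aux = _profiled_nll(np.zeros(0), y, X, Zs, None)
        theta = np.zeros(0)
    else:
        x0 = np.full(n_var, -0.5)
        if v is not None:
            x0[-1] = 0.0
        res = optimize.minimize(
            lambda th: _profiled_nll(th, y, X, Zs, v)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000},
        )
        theta = res.x
        nll, aux = _profiled_nll(theta, y, X, Zs, v)
    if aux is None:
        raise SingularFitError("mixed-model likelihood is degenerate at the optimum")
    beta, sigma2, XtVX, c, low = aux
    cov_beta = sigma2 * linalg.inv(XtVX)
    return theta, beta, sigma2, cov_beta, -nll


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> LmmFit:
    """Fit the model by ML; rows with non-finite response/predictors drop.

    Raises :class:`AliasedTermError` when the fixed-effects design is rank
    deficient and :class:`SingularFitError` when the likelihood degenerates.
    """
    ydf, Xdf = dmatrices(spec.formula, data, return_type="dataframe")
    di = Xdf.design_info  # captured before row filtering drops the attribute
    keep = np.isfinite(ydf.to_numpy()).ravel() & np.isfinite(Xdf.to_numpy()).all(axis=1)
    ydf, Xdf = ydf[keep], Xdf[keep]
    n_dropped = len(data) - len(ydf)  # NaN rows (patsy) + non-finite rows
    used_index = ydf.index
    y = ydf.to_numpy().ravel()
    X = Xdf.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the aliased columns for the error message
        _, r = np.linalg.qr(X)
        aliased = [Xdf.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise AliasedTermError(f"aliased (collinear) design columns: {aliased}")

    Zs = [_indicator(data.loc[used_index, g]) for g in spec.groups]
    if spec.groups and min(Z.shape[1] for Z in Zs) < 2:
        raise SingularFitError("grouping factor with fewer than 2 levels")

    v = None
    if spec.variance == "exp":
        if spec.variance_covariate is not None:
            v = data.loc[used_index, spec.variance_covariate].to_numpy(dtype=float)
        else:
            beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            v = X @ beta_ols
        v = v - v.mean()
        scale = np.abs(v).max()
        if scale > 0:
            v = v / scale
    elif spec.variance != "homoscedastic":
        raise ValueError(f"unknown variance structure '{spec.variance}'")

    theta, beta, sigma2, cov_beta, ll = _fit_core(y, X, Zs, v)
    names = list(Xdf.columns)
    term_slices = {
        t.name(): np.arange(*di.term_name_slices[t.name()].indices(len(names)))
        for t in di.terms
    }
    ratios = {g: float(np.exp(2 * theta[k])) for k, g in enumerate(spec.groups)}
    delta = float(theta[len(spec.groups)]) if v is not None else 0.0
    k_params = X.shape[1] + 1 + len(Zs) + (1 if v is not None else 0)
    return LmmFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma2=float(sigma2),
        variance_ratios=ratios,
        delta=delta,
        loglik=float(ll),
        n_obs=len(y),
        n_dropped=n_dropped,
        term_slices=term_slices,
        k_params=k_params,
        _y=y,
        _X=X,
        _Zs=Zs,
        _v=v,
    )


def type3_wald(fit: LmmFit, mode: str = "wald") -> pd.DataFrame:
    """Per-term joint chi-square table (type III: each term given all others).

    ``mode="wald"`` tests b' C^{-1} b on the ML coefficient covariance;
    ``mode="lr"`` refits the model without the term's columns and uses
    2*(ll_full - ll_reduced).  Requires sum-to-zero coding of categorical
    terms for the marginal hypotheses to be the conventional ones.
    """
    if mode not in {"wald", "lr"}:
        raise ValueError("mode must be 'wald' or 'lr'")
    rows = []
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    for term, idx in fit.term_slices.items():
        if term == "Intercept" or len(idx) == 0:
            continue
        if mode == "wald":
            b = beta[idx]
            C = cov[np.ix_(idx, idx)]
            try:
                chi2 = float(b @ linalg.solve(C, b, assume_a="pos"))
            except linalg.LinAlgError as exc:
                raise AliasedTermError(f"term '{term}' has singular covariance") from exc
        else:
            keep = np.setdiff1d(np.arange(len(beta)), idx)
            _, _, _, _, ll0 = _fit_core(fit._y, fit._X[:, keep], fit._Zs, fit._v)
            chi2 = max(0.0, 2.0 * (fit.loglik - ll0))
        df = len(idx)
        rows.append(
            {"term": term, "chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}
        )
    return pd.DataFrame(rows).set_index("term")


def significance_band(p: float) -> str:
    """The annotation convention: *** <0.001, ** <0.01, * <0.05, . <0.1."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""
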