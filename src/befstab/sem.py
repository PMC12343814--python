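"""Multi-group piecewise structural equation modelling.

A piecewise SEM is a DAG of observed variables in which every endogenous
node is fitted by its own (mixed) regression on its parents.  Model-level
fit is judged through the d-separation basis set: one conditional-
independence claim per non-adjacent pair of variables, conditioned on the
union of the pair's parents (pairs declared as correlated errors are
exempt).  Each claim is tested by regressing the topologically later
variable on the earlier one plus the conditioning set and taking the
earlier variable's coefficient P value; the claims combine into Fisher's

    C = -2 * sum(ln P_i),   df = 2k,   P = upper tail of chi2(df) at C,

which is chi-square distributed when the DAG is consistent with the data.
AIC = C + 2K with K the number of parameters estimated across component
models.  In the multi-group analysis each path is tested for a path-by-
group interaction: significant paths are freed ("unconstrained", group-
specific coefficients), the rest stay constrained to a common coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from befstab.lmm import LmmFit, ModelSpec, fit_lmm, type3_wald


class CyclicModelError(ValueError):
    pass


class GroupTooSmallError(ValueError):
    pass


@dataclass
class SemModel:
    nodes: list
    edges: list  # (parent, child) directed
    correlated_errors: list = field(default_factory=list)  # undirected pairs
    groups: list = field(default_factory=list)  # random-intercept columns
    variance: str = "homoscedastic"

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise CyclicModelError("directed edges must form a DAG")
        for pair in self.correlated_errors:
            a, b = tuple(pair)
            if g.has_edge(a, b) or g.has_edge(b, a):
                raise ValueError(f"correlated-error pair {a}~~{b} duplicates a directed edge")
        return g

    def endogenous(self) -> dict:
        g = self.graph()
        return {n: sorted(g.predecessors(n)) for n in self.nodes if g.in_degree(n) > 0}


@dataclass(frozen=True)
class IndependenceClaim:
    x: str  # topologically earlier
    y: str  # later; regressed on x + conditioning set
    conditioning: tuple

    def __str__(self):
        cond = ", ".join(self.conditioning) or "{}"
        return f"{self.x} _||_ {self.y} | {{{cond}}}"


def basis_set(model: SemModel) -> list:
    """The union-of-parents d-separation basis set, deterministically ordered.

    One claim per pair of variables with no directed edge either way and no
    declared error correlation, conditioned on the union of both variables'
    parents.  Ordering is topological (lexicographic tie-break) on the later
    variable, then the earlier.
    """
    g = model.graph()
    order = list(nx.lexicographical_topological_sort(g))
    pos = {n: i for i, n in enumerate(order)}
    exempt = {frozenset(p) for p in model.correlated_errors}
    claims = []
    for j, y in enumerate(order):
        for x in order[:j]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            if frozenset((x, y)) in exempt:
                continue
            cond = (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y}
            claims.append(IndependenceClaim(x, y, tuple(sorted(cond, key=pos.get))))
    return claims


def fishers_c(p_values) -> tuple:
    """Combine claim P values: returns (C, df, global P)."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("P values must lie in [0, 1]")
    df = 2 * len(p)
    if len(p) == 0:
        return 0.0, 0, 1.0
    if (p == 0).any():
        return np.inf, df, 0.0
    c = float(-2.0 * np.sum(np.log(p)))
    return c, df, float(stats.chi2.sf(c, df))


@dataclass
class SemFit:
    model: SemModel
    paths: pd.DataFrame  # response, predictor, group, coef, se, p, std_coef, constrained
    claims: pd.DataFrame  # x, y, conditioning, p
    fisher_c: float
    df: int
    p_value: float
    aic: float
    k_params: int
    component_fits: dict = field(repr=False, default_factory=dict)

    def pruning_candidates(self, threshold: float = 0.1) -> pd.DataFrame:
        """Paths at or above the display threshold — reported, never auto-removed."""
        return self.paths[self.paths["p"] >= threshold]


def _sd(data: pd.DataFrame, col: str) -> float:
    v = data[col].to_numpy(dtype=float)
    v = v[np.isfinite(v)]
    return float(np.std(v, ddof=1)) if len(v) > 1 else np.nan


def _coef_p(fit: LmmFit, name: str) -> tuple:
    se = float(np.sqrt(fit.cov_params.loc[name, name]))
    b = float(fit.params[name])
    z = b / se
    return b, se, 2 * float(stats.norm.sf(abs(z)))


def _is_deterministic(fit: LmmFit, tol: float = 1e-8) -> bool:
    """True when the residual variance is negligible against the response's.

    A response that is an exact function of its predictors (e.g. log
    community stability given log asynchrony and log species stability,
    which sum to it identically) makes coefficient tests meaningless —
    and makes any conditional-independence claim about it trivially true.
    """
    var_y = float(np.var(fit._y))
    return var_y > 0 and fit.sigma2 < tol * var_y


def _claim_pvalues(model: SemModel, claims, data, extra_rhs: str = "") -> list:
    rows = []
    for cl in claims:
        rhs = " + ".join(list(cl.conditioning) + ([extra_rhs] if extra_rhs else []) + [cl.x]) or "1"
        spec = ModelSpec(f"{cl.y} ~ {rhs}", groups=model.groups, variance=model.variance)
        fit = fit_lmm(spec, data)
        if _is_deterministic(fit):
            p = 1.0  # y is an exact function of its parents: independence is vacuous
        else:
            _, _, p = _coef_p(fit, cl.x)
        rows.append({"x": cl.x, "y": cl.y, "conditioning": ";".join(cl.conditioning), "p": p})
    return rows


def fit_psem(model: SemModel, data: pd.DataFrame) -> SemFit:
    """Single-group piecewise SEM fit."""
    paths, fits = [], {}
    k_total = 0
    for node, parents in model.endogenous().items():
        spec = ModelSpec(f"{node} ~ {' + '.join(parents)}", groups=model.groups, variance=model.variance)
        try:
            fit = fit_lmm(spec, data)
        except Exception as exc:
            raise type(exc)(f"component model for '{node}': {exc}") from exc
        fits[node] = fit
        k_total += fit.k_params
        sd_y = _sd(data, node)
        for parent in parents:
            b, se, p = _coef_p(fit, parent)
            paths.append(
                {
                    "response": node,
                    "predictor": parent,
                    "group": "all",
                    "coef": b,
                    "se": se,
                    "p": p,
                    "std_coef": b * _sd(data, parent) / sd_y,
                    "constrained": True,
                }
            )
    claim_rows = _claim_pvalues(model, basis_set(model), data)
    c, df, p_global = fishers_c([r["p"] for r in claim_rows])
    return SemFit(
        model=model,
        paths=pd.DataFrame(paths),
        claims=pd.DataFrame(claim_rows, columns=["x", "y", "conditioning", "p"]),
        fisher_c=c,
        df=df,
        p_value=p_global,
        aic=c + 2 * k_total,
        k_params=k_total,
        component_fits=fits,
    )


def multigroup(
    model: SemModel,
    data: pd.DataFrame,
    group_col: str,
    alpha: float = 0.05,
) -> SemFit:
    """Multi-group fit with per-path constrained/unconstrained decisions.

    For each path the path-by-group interaction is tested (type-III Wald)
    in the component model with all paths interacting; significant paths
    (P < ``alpha``) are unconstrained and reported per group, the rest keep
    a pooled coefficient.  Fisher's C is assembled from claims tested on
    the group-aware component models (group main effect included).
    """
    levels = sorted(data[group_col].dropna().unique())
    if len(levels) < 2:
        return fit_psem(model, data)
    counts = data[group_col].value_counts()
    n_nodes = len(model.nodes)
    small = [g for g in levels if counts.get(g, 0) < n_nodes + 2]
    if small:
        raise GroupTooSmallError(f"group(s) with too few rows for the SEM: {small}")
    gterm = f"C({group_col}, Sum)"

    paths, fits = [], {}
    k_total = 0
    for node, parents in model.endogenous().items():
        full_rhs = " + ".join([gterm] + parents + [f"{p}:{gterm}" for p in parents])
        full = fit_lmm(
            ModelSpec(f"{node} ~ {full_rhs}", groups=model.groups, variance=model.variance), data
        )
        if _is_deterministic(full):
            # exact functional response: no residual, no group contrast to test
            unconstrained = set()
        else:
            wald = type3_wald(full)
            unconstrained = {
                p for p in parents if wald.loc[f"{p}:{gterm}", "p"] < alpha
            }
        kept = [gterm] + parents + [f"{p}:{gterm}" for p in sorted(unconstrained)]
        refit = fit_lmm(
            ModelSpec(f"{node} ~ {' + '.join(kept)}", groups=model.groups, variance=model.variance),
            data,
        )
        fits[node] = refit
        k_total += refit.k_params
        sd_y_all = _sd(data, node)
        for parent in parents:
            if parent in unconstrained:
                for lvl in levels:
                    sub = data[data[group_col] == lvl]
                    gfit = fit_lmm(
                        ModelSpec(
                            f"{node} ~ {' + '.join(parents)}",
                            groups=model.groups,
                            variance=model.variance,
                        ),
                        sub,
                    )
                    b, se, p = _coef_p(gfit, parent)
                    paths.append(
                        {
                            "response": node,
                            "predictor": parent,
                            "group": str(lvl),
                            "coef": b,
                            "se": se,
                            "p": p,
                            "std_coef": b * _sd(sub, parent) / _sd(sub, node),
                            "constrained": False,
                        }
                    )
            else:
                b, se, p = _coef_p(refit, parent)
                for lvl in levels:
                    paths.append(
                        {
                            "response": node,
                            "predictor": parent,
                            "group": str(lvl),
                            "coef": b,
                            "se": se,
                            "p": p,
                            "std_coef": b * _sd(data, parent) / sd_y_all,
                            "constrained": True,
                        }
                    )
    claim_rows = _claim_pvalues(model, basis_set(model), data, extra_rhs=gterm)
    c, df, p_global = fishers_c([r["p"] for r in claim_rows])
    return SemFit(
        model=model,
        paths=pd.DataFrame(paths),
        claims=pd.DataFrame(claim_rows, columns=["x", "y", "conditioning", "p"]),
        fisher_c=c,
        df=df,
        p_value=p_global,
        aic=c + 2 * k_total,
        k_params=k_total,
        component_fits=fits,
    )


def default_sem_model(groups: list | None = None) -> SemModel:
    """The a-priori causal structure linking richness, functioning and stability.

    log richness drives the four mechanisms (CE, SE, asynchrony, species
    stability); CE/SE drive productivity and are tested as drivers of the
    stability mechanisms; asynchrony and species stability drive community
    stability.  CE~~SE and asynchrony~~species-stability carry correlated
    errors.
    """
    return SemModel(
        nodes=[
            "log_sr",
            "ce",
            "se",
            "asynchrony_log",
            "species_stability_log",
            "productivity_log",
            "community_stability_log",
        ],
        edges=[
            ("log_sr", "ce"),
            ("log_sr", "se"),
            ("log_sr", "asynchrony_log"),
            ("log_sr", "species_stability_log"),
            ("ce", "productivity_log"),
            ("se", "productivity_log"),
            ("ce", "asynchrony_log"),
            ("ce", "species_stability_log"),
            ("se", "asynchrony_log"),
            ("se", "species_stability_log"),
            ("asynchrony_log", "community_stability_log"),
            ("species_stability_log", "community_stability_log"),
        ],
        correlated_errors=[("ce", "se"), ("asynchrony_log", "species_stability_log")],
        groups=list(groups) if groups is not None else ["ring_id"],
    )


def to_dot(fit: SemFit, threshold: float = 0.1) -> str:
    """DOT rendering of the fitted graph (paths below ``threshold`` shown)."""
    lines = ["digraph sem {", "  rankdir=LR;"]
    for n in fit.model.nodes:
        lines.append(f'  "{n}";')
    shown = fit.paths[fit.paths["p"] < threshold]
    for r in shown.itertuples():
        style = "solid" if r.coef >= 0 else "dashed"
        color = "black" if r.constrained else "red"
        lines.append(
            f'  "{r.predictor}" -> "{r.response}" '
            f'[label="{r.std_coef:.2f} ({r.group})", style={style}, color={color}];'
        )
    for a, b in fit.model.correlated_errors:
        lines.append(f'  "{a}" -> "{b}" [dir=both, style=dotted];')
    lines.append("}")
    return "\n".join(lines)
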