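import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from befstab.sem import (
    CyclicModelError,
    SemModel,
    basis_set,
    default_sem_model,
    fishers_c,
    fit_psem,
    multigroup,
    to_dot,
)


def chain_model(groups=()):
    return SemModel(nodes=["x", "y", "z"], edges=[("x", "y"), ("y", "z")], groups=list(groups))


def chain_data(seed, n=200, direct=0.0, bx=1.0, by=1.0, noise=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    y = bx * x + rng.normal(0, noise, n)
    z = by * y + direct * x + rng.normal(0, noise, n)
    return pd.DataFrame({"x": x, "y": y, "z": z})


def test_chain_basis_set():
    claims = basis_set(chain_model())
    assert len(claims) == 1
    cl = claims[0]
    assert (cl.x, cl.y, cl.conditioning) == ("x", "z", ("y",))


def test_diamond_basis_set():
    model = SemModel(
        nodes=["x", "y", "z", "w"],
        edges=[("x", "y"), ("x", "z"), ("y", "w"), ("z", "w")],
    )
    claims = basis_set(model)
    as_tuples = {(c.x, c.y, frozenset(c.conditioning)) for c in claims}
    assert as_tuples == {
        ("y", "z", frozenset({"x"})),
        ("x", "w", frozenset({"y", "z"})),
    }


def test_saturated_dag_has_empty_basis():
    model = SemModel(nodes=["a", "b", "c"], edges=[("a", "b"), ("a", "c"), ("b", "c")])
    assert basis_set(model) == []
    c, df, p = fishers_c([])
    assert (c, df, p) == (0.0, 0, 1.0)


def test_correlated_errors_exempt_pairs():
    model = SemModel(
        nodes=["x", "y", "z"], edges=[("x", "y"), ("x", "z")],
        correlated_errors=[("y", "z")],
    )
    assert basis_set(model) == []


def test_cycle_rejected():
    with pytest.raises(CyclicModelError):
        basis_set(SemModel(nodes=["a", "b"], edges=[("a", "b"), ("b", "a")]))


def random_dag(rng, n_nodes, p_edge=0.4):
    order = [f"v{i}" for i in range(n_nodes)]
    edges = [
        (order[i], order[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    return SemModel(nodes=order, edges=edges)


def test_basis_claims_are_valid_dseparations():
    """Every emitted claim is a true d-separation (networkx oracle, 200 DAGs)."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        model = random_dag(rng, int(rng.integers(3, 7)))
        g = model.graph()
        for cl in basis_set(model):
            assert nx.is_d_separator(g, {cl.x}, {cl.y}, set(cl.conditioning)), (
                f"claim {cl} is not d-separated in {sorted(g.edges)}"
            )


def test_basis_covers_every_nonadjacent_pair():
    rng = np.random.default_rng(7)
    for _ in range(50):
        model = random_dag(rng, 5)
        g = model.graph()
        claimed = {frozenset((c.x, c.y)) for c in basis_set(model)}
        expected = {
            frozenset(p)
            for p in itertools.combinations(model.nodes, 2)
            if not (g.has_edge(*p) or g.has_edge(*reversed(p)))
        }
        assert claimed == expected


def test_fishers_c_trivial_and_closed_form():
    c, df, p = fishers_c([1.0])
    assert (c, df, p) == (0.0, 2, 1.0)
    c, df, p = fishers_c([0.5, 0.5])
    assert c == pytest.approx(2.7726, abs=1e-4)
    assert df == 4
    # closed form e^{-C/2} (1 + C/2)
    assert p == pytest.approx(np.exp(-c / 2) * (1 + c / 2), rel=1e-12)
    assert p == pytest.approx(0.5966, abs=1e-4)


def test_fishers_c_zero_p_is_rejection():
    c, df, p = fishers_c([0.0, 0.5])
    assert np.isinf(c) and p == 0.0


def test_fishers_c_monotone_and_p1_adds_nothing():
    base = fishers_c([0.3, 0.6])
    lower = fishers_c([0.2, 0.6])
    assert lower[0] > base[0]
    extended = fishers_c([0.3, 0.6, 1.0])
    assert extended[0] == pytest.approx(base[0])
    assert extended[1] == base[1] + 2


def test_published_scale_chi_square_tail():
    # chi2(16) upper tail at 16.112 and the AIC arithmetic C + 2K
    assert stats.chi2.sf(16.112, 16) == pytest.approx(0.445, abs=5e-4)
    assert 16.112 + 2 * 32 == pytest.approx(80.112)


def test_standardized_coefficient_perfect_relation():
    data = pd.DataFrame({"x": np.linspace(-2, 2, 50)})
    data["y"] = 2.0 * data["x"]
    fit = fit_psem(SemModel(nodes=["x", "y"], edges=[("x", "y")]), data)
    row = fit.paths.iloc[0]
    assert row["std_coef"] == pytest.approx(1.0)
    assert fit.aic == pytest.approx(fit.fisher_c + 2 * fit.k_params)


def test_standardized_coefficients_scale_invariant():
    data = chain_data(seed=5, n=300)
    f1 = fit_psem(chain_model(), data)
    rescaled = data.assign(x=data.x * 100 + 3, y=data.y / 7, z=data.z * 0.01)
    f2 = fit_psem(chain_model(), rescaled)
    a = f1.paths.set_index(["response", "predictor"])["std_coef"]
    b = f2.paths.set_index(["response", "predictor"])["std_coef"]
    for k in a.index:
        assert a[k] == pytest.approx(b[k], rel=1e-6)


def test_dsep_power_detects_omitted_direct_path():
    ps = [
        fit_psem(chain_model(), chain_data(seed=3000 + i, n=150, direct=0.3)).p_value
        for i in range(60)
    ]
    assert np.median(ps) < 0.05


def test_single_group_multigroup_reduces_to_psem():
    data = chain_data(seed=8, n=150).assign(grp="only")
    mg = multigroup(chain_model(), data, "grp")
    single = fit_psem(chain_model(), data)
    assert mg.fisher_c == pytest.approx(single.fisher_c)
    pd.testing.assert_frame_equal(mg.paths, single.paths)


def test_deterministic_response_claims_are_vacuous():
    """A response that is an exact function of its parents yields claim P = 1."""
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 120)
    a = x + rng.normal(0, 1, 120)
    b = -x + rng.normal(0, 1, 120)
    s = a + b  # deterministic given its two parents
    data = pd.DataFrame({"x": x, "a": a, "b": b, "s": s})
    model = SemModel(
        nodes=["x", "a", "b", "s"],
        edges=[("x", "a"), ("x", "b"), ("a", "s"), ("b", "s")],
        correlated_errors=[("a", "b")],
    )
    fit = fit_psem(model, data)
    claim = fit.claims.set_index(["x", "y"])
    assert claim.loc[("x", "s"), "p"] == 1.0


def test_dot_output_mentions_paths():
    data = chain_data(seed=10, n=100)
    dot = to_dot(fit_psem(chain_model(), data))
    assert dot.startswith("digraph") and '"x" -> "y"' in dot


def test_default_model_shape():
    model = default_sem_model()
    claims = basis_set(model)
    assert len(claims) == 7  # df = 14 before any simplification
    g = model.graph()
    assert nx.is_directed_acyclic_graph(g)
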