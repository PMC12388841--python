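"""Polynomial response-surface fitting, model selection and optimization."""

import numpy as np
import pytest

import surfopt as so
from surfopt.design import DesignError
from surfopt.rsm import build_design_matrix, term_names
from surfopt.synthetic import GeneratorSpec, generate

from conftest import make_model


def test_design_matrix_rows():
    center = build_design_matrix(np.array([[0.0, 0.0, 0.0]]), "quadratic")
    assert center.tolist() == [[1, 0, 0, 0, 0, 0, 0, 0, 0, 0]]
    corner = build_design_matrix(np.array([[1.0, 1.0, 1.0]]), "quadratic")
    assert corner.tolist() == [[1.0] * 10]


def test_design_matrix_full_rank_on_factorial():
    coded = np.array([p.coded for p in so.full_factorial(so.DEFAULT_FACTORS)])
    for family, k in [("linear", 4), ("2fi", 7), ("quadratic", 10), ("cubic", 17)]:
        X = build_design_matrix(coded, family)
        assert X.shape == (27, k)
        assert np.linalg.matrix_rank(X) == k


def test_unknown_family_rejected():
    with pytest.raises(DesignError):
        term_names("quartic")


def test_cubic_family_excludes_aliased_pure_cubes():
    assert "x1^3" not in term_names("cubic")
    assert "x1*x2*x3" in term_names("cubic")


@pytest.mark.parametrize("seed", range(10))
@pytest.mark.parametrize("family", so.FAMILIES)
def test_ols_matches_normal_equations_oracle(seed, family):
    """lstsq solution equals the brute-force normal-equations solve."""
    rng = np.random.default_rng(seed)
    spec = GeneratorSpec(true_beta=tuple(rng.normal(0, 1, 10)), noise_sd=0.1, seed=seed)
    ds = generate(spec)
    model = so.fit_ols(ds, family)
    X = build_design_matrix(ds.coded_matrix(), family)
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ ds.response)
    assert np.allclose(model.beta, beta_oracle, rtol=1e-8, atol=1e-10)


def test_ols_matches_statsmodels(fixture_dataset):
    sm = pytest.importorskip("statsmodels.api")
    X = build_design_matrix(fixture_dataset.coded_matrix(), "quadratic")
    fit = sm.OLS(fixture_dataset.response, X).fit()
    model = so.fit_ols(fixture_dataset, "quadratic")
    assert np.allclose(model.beta, fit.params, rtol=1e-10)
    assert model.r2 == pytest.approx(fit.rsquared, rel=1e-10)
    assert model.adj_r2 == pytest.approx(fit.rsquared_adj, rel=1e-10)


def test_noise_free_recovery_is_exact():
    beta = (3.0, -0.1, -0.5, 0.1, 0.05, 0.0, -0.02, -0.4, -0.7, -0.15)
    ds = generate(GeneratorSpec(true_beta=beta, noise_sd=0.0))
    model = so.fit_ols(ds, "quadratic")
    assert np.allclose(model.beta, beta, atol=1e-8)
    assert model.sse < 1e-16


def test_fixture_quadratic_matches_published_fit(fixture_quadratic):
    m = fixture_quadratic
    assert m.r2 == pytest.approx(0.992, rel=0.01)
    assert m.coef("1") == pytest.approx(3.94, rel=0.01)
    assert m.coef("x2") == pytest.approx(-0.478, rel=0.02)
    assert m.coef("x2^2") == pytest.approx(-0.714, rel=0.02)


def test_anova_decomposition(fixture_dataset, fixture_quadratic):
    tab = so.anova_table(fixture_quadratic, fixture_dataset)
    ss = dict(zip(tab["source"], tab["SS"]))
    assert ss["regression"] + ss["residual"] == pytest.approx(ss["total"], rel=1e-8)
    p_reg = float(tab.loc[tab["source"] == "regression", "p"].iloc[0])
    assert p_reg < 0.05


def test_anova_perfect_fit():
    ds = generate(GeneratorSpec(noise_sd=0.0))
    m = so.fit_ols(ds, "quadratic")
    tab = so.anova_table(m, ds)
    assert float(tab.loc[tab["source"] == "residual", "SS"].iloc[0]) < 1e-16


def test_r2_monotone_across_nested_families(fixture_dataset):
    r2 = [so.fit_ols(fixture_dataset, fam).r2 for fam in ("linear", "2fi", "quadratic", "cubic")]
    assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))


def test_compare_models_ranks_quadratic_over_simpler(fixture_dataset):
    ranked = so.compare_models(fixture_dataset)
    order = [m.family for m in ranked]
    assert order.index("quadratic") < order.index("linear")
    assert order.index("quadratic") < order.index("2fi")


def test_select_model_picks_quadratic_on_fixture(fixture_dataset):
    assert so.select_model(fixture_dataset).family == "quadratic"


def test_linear_truth_selects_linear():
    """With a purely linear generator and small noise, the sequential
    partial-F selection keeps the linear family (richer families only
    absorb noise, so their extra terms are jointly insignificant with
    high probability; checked across seeds)."""
    beta = (3.0, 0.4, -0.3, 0.2, 0, 0, 0, 0, 0, 0)
    picks = [
        so.select_model(generate(GeneratorSpec(true_beta=beta, noise_sd=0.001, seed=s))).family
        for s in range(8)
    ]
    assert picks.count("linear") >= 7


def test_stationary_point_of_concave_sphere():
    m = make_model([1, 0, 0, 0, 0, 0, 0, -1, -1, -1])
    sp = so.stationary_point(m)
    assert sp.nature == "maximum"
    assert sp.coded == pytest.approx((0, 0, 0), abs=1e-12)
    assert sp.predicted_response == pytest.approx(1.0)
    assert sp.inside_box


def test_stationary_point_saddle():
    m = make_model([0, 0, 0, 0, 0, 0, 0, 1, -1, -1])
    assert so.stationary_point(m).nature == "saddle"


def test_stationary_point_singular_hessian():
    m = make_model([0, 1, 0, 0, 0, 0, 0, 0, -1, -1])
    with pytest.raises(DesignError, match="[Ss]ingular"):
        so.stationary_point(m)


def test_fixture_stationary_point_is_interior_maximum(fixture_quadratic):
    sp = so.stationary_point(fixture_quadratic)
    assert sp.nature == "maximum"
    assert sp.inside_box
    # time coordinate from the closed-form gradient solve is near 40 min
    assert 35 < sp.natural[1] < 45


def test_maximize_agrees_with_stationary_point(fixture_quadratic):
    sp = so.stationary_point(fixture_quadratic)
    opt = so.maximize_in_box(fixture_quadratic)
    assert np.allclose(opt.coded, sp.coded, atol=1e-6)
    assert opt.predicted_response == pytest.approx(sp.predicted_response, abs=1e-9)


def test_maximize_linear_hits_face():
    m = make_model([0, 1, 0, 0], family="linear")
    opt = so.maximize_in_box(m)
    assert opt.coded[0] == pytest.approx(1.0)
    assert not opt.inside_box


def test_fixture_box_optimum_location(fixture_quadratic):
    opt = so.maximize_in_box(fixture_quadratic)
    assert 40 < opt.natural[0] < 47  # temperature degC
    assert 40 < opt.natural[2] < 60  # ethanol %
    assert opt.inside_box


def test_surface_grid_center_is_intercept(fixture_quadratic):
    grid = so.surface_grid(fixture_quadratic, "ethanol", 0.0, resolution=3)
    assert grid.predicted[1, 1] == pytest.approx(fixture_quadratic.coef("1"))
    assert grid.predicted[1, 1] == pytest.approx(3.94, rel=0.01)


def test_surface_grid_max_matches_restricted_box_search(fixture_quadratic):
    grid = so.surface_grid(fixture_quadratic, "ethanol", 0.0, resolution=201)
    i, j = np.unravel_index(np.argmax(grid.predicted), grid.predicted.shape)
    # slice optimum from an independent fine 2-D scan of the same slice
    axis = np.linspace(-1, 1, 2001)
    A1, A2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.column_stack([A1.ravel(), A2.ravel(), np.zeros(A1.size)])
    vals = fixture_quadratic.predict_coded(pts)
    assert grid.predicted[i, j] == pytest.approx(vals.max(), abs=1e-3)


def test_surface_grid_unknown_factor(fixture_quadratic):
    with pytest.raises(DesignError):
        so.surface_grid(fixture_quadratic, "pressure")
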