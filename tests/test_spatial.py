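import numpy as np
import pandas as pd
import pytest

from betascape.grids import ENV_COLUMNS
from betascape.spatial import (
    SpatialError,
    distance_band_weights,
    fit_spatial_regression,
    modified_t_test,
    moran_profile,
    multimodel_average,
    piecewise_latitudinal_fit,
    prepare_covariates,
    select_neighbor_distance,
    standardize,
    weights_from_cells,
)
from helpers import make_cells


def env_table(cells, rng):
    env = pd.DataFrame({"cell_id": cells["cell_id"]})
    for col in ENV_COLUMNS:
        env[col] = rng.uniform(0.5, 2.0, len(cells))
    env["human_modification"] = rng.uniform(0, 1, len(cells))
    return env


def sar_error_data(rng, cells, rho, beta, sigma=1.0):
    """Draw y = X beta + u with u = rho W u + eps on the given lattice."""
    W = weights_from_cells(cells, 300.0)
    n = len(cells)
    X = rng.standard_normal((n, len(beta)))
    eps = rng.standard_normal(n) * sigma
    u = np.linalg.solve(np.eye(n) - rho * W.matrix, eps)
    return X @ np.asarray(beta) + u, X, W


# ---------------------------------------------------------------- covariates


def test_neighborhood_mean_and_transforms(rng):
    cells = make_cells(5, 5)
    env = env_table(cells, rng)
    env["temperature_anomaly"] = 4.0  # uniform -> window mean = 4 everywhere
    with pytest.raises(SpatialError, match="zero-variance"):
        prepare_covariates(env, cells)
    env["temperature_anomaly"] = rng.uniform(1, 8, len(cells))
    X = prepare_covariates(env, cells, radius=2)
    assert list(X.columns) == list(ENV_COLUMNS)
    np.testing.assert_allclose(X.mean(), 0, atol=1e-10)
    np.testing.assert_allclose(X.std(ddof=1), 1, atol=1e-10)


def test_sqrt_transform_hand_check(rng):
    cells = make_cells(1, 3)
    env = env_table(cells, rng)
    env["human_modification"] = [0.0, 0.25, 1.0]
    X = prepare_covariates(env, cells, radius=1, neighborhood_mean=False)
    v = np.sqrt([0.0, 0.25, 1.0])
    expected = (v - v.mean()) / v.std(ddof=1)
    np.testing.assert_allclose(X["human_modification"], expected, atol=1e-12)


# ------------------------------------------------------------------ OLS / SAR


def test_ols_exact_on_noiseless_linear_data(rng):
    cells = make_cells(6, 6)
    X = rng.standard_normal((36, 2))
    y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
    fit = fit_spatial_regression(y, X, mode="ols")
    np.testing.assert_allclose(fit.params, [1.0, 2.0, -0.5], atol=1e-10)
    np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)


def test_sar_agrees_with_ols_when_no_autocorrelation(rng):
    cells = make_cells(12, 12)
    y, X, W = sar_error_data(rng, cells, rho=0.0, beta=[1.0, -0.5])
    ols = fit_spatial_regression(y, X, mode="ols")
    fixed = fit_spatial_regression(y, X, W, mode="sar_error", fix_rho=0.0)
    np.testing.assert_allclose(fixed.params, ols.params, atol=1e-10)
    free = fit_spatial_regression(y, X, W, mode="sar_error")
    assert abs(free.rho) < 1.96 * free.rho_se + 0.05  # rho CI covers zero


def test_sar_recovers_error_coefficient(rng):
    cells = make_cells(15, 15)
    y, X, W = sar_error_data(rng, cells, rho=0.7, beta=[1.0])
    fit = fit_spatial_regression(y, X, W, mode="sar_error")
    assert 0.4 < fit.rho < 0.95
    assert fit.params.iloc[1] == pytest.approx(1.0, abs=0.3)
    assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)


def test_singular_design_rejected(rng):
    cells = make_cells(5, 5)
    x = rng.standard_normal(25)
    X = np.column_stack([x, 2 * x])
    with pytest.raises(SpatialError, match="singular"):
        fit_spatial_regression(rng.standard_normal(25), X, mode="ols")


# ------------------------------------------------------------------ Moran's I


def test_moran_profile_gradient_and_noise(rng):
    cells = make_cells(10, 10)
    gradient = cells["row"].to_numpy(float)
    prof = moran_profile(gradient, cells)
    assert prof.moran_i[0] > 0.5  # smooth field: strong short-range structure

    n = len(cells)
    iid = rng.standard_normal(n)
    prof_iid = moran_profile(iid, cells)
    # permutation null for the first class
    null = []
    for _ in range(99):
        null.append(moran_profile(rng.permutation(iid), cells).moran_i[0])
    spread = np.std(null, ddof=1)
    assert abs(prof_iid.moran_i[0] - (-1 / (n - 1))) < 3.5 * spread

    with pytest.raises(SpatialError, match="constant"):
        moran_profile(np.ones(n), cells)


def test_sar_whitening_reduces_residual_autocorrelation(rng):
    reductions = []
    cells = make_cells(12, 12)
    for _ in range(9):
        y, X, W = sar_error_data(rng, cells, rho=0.8, beta=[1.0])
        ols = fit_spatial_regression(y, X, mode="ols")
        sar = fit_spatial_regression(y, X, W, mode="sar_error")
        m_ols = moran_profile(ols.residuals, cells).min_rsa
        m_sar = moran_profile(sar.residuals, cells).min_rsa
        reductions.append(m_sar < m_ols)
    assert sum(reductions) >= 5  # median improvement


def test_distance_selection_prefers_generating_scale(rng):
    cells = make_cells(10, 10)
    hits = 0
    for _ in range(10):
        y, X, W = sar_error_data(rng, cells, rho=0.85, beta=[1.0])
        sel = select_neighbor_distance(
            standardize(y), X, cells, distances=(300, 600, 1000)
        )
        hits += sel.best_distance == 300.0
    assert hits >= 6
    single = select_neighbor_distance(standardize(y), X, cells, distances=(300,))
    assert single.best_distance == 300.0


def test_weights_invariants(rng):
    cells = make_cells(6, 6)
    W = weights_from_cells(cells, 300.0)
    np.testing.assert_allclose(W.matrix.sum(axis=1), 1.0)
    assert np.all(np.diag(W.matrix) == 0)
    with pytest.raises(SpatialError, match="isolated"):
        distance_band_weights(np.array([[0.0, 0.0], [1000.0, 0.0]]), 300.0)


# ------------------------------------------------------- multimodel inference


def test_multimodel_closed_form_with_one_covariate(rng):
    cells = make_cells(8, 8)
    y, X, W = sar_error_data(rng, cells, rho=0.3, beta=[0.8])
    Xdf = pd.DataFrame(X, columns=["x0"])
    avg = multimodel_average(standardize(y), Xdf, W)
    assert len(avg.models) == 2
    assert avg.models["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    w_full = avg.models.set_index("terms").loc["x0", "weight"]
    assert avg.coefficients.loc["x0", "importance"] == pytest.approx(w_full)
    # single containing model: conditional average equals its coefficient
    full = fit_spatial_regression(standardize(y), Xdf, W, mode="sar_error")
    assert avg.coefficients.loc["x0", "coef"] == pytest.approx(full.params["x0"])


def test_importance_invariant_to_covariate_order(rng):
    cells = make_cells(8, 8)
    y, X, W = sar_error_data(rng, cells, rho=0.3, beta=[1.0, 0.0])
    Xdf = pd.DataFrame(X, columns=["a", "b"])
    avg1 = multimodel_average(standardize(y), Xdf, W)
    avg2 = multimodel_average(standardize(y), Xdf[["b", "a"]], W)
    for cov in ("a", "b"):
        assert avg1.coefficients.loc[cov, "importance"] == pytest.approx(
            avg2.coefficients.loc[cov, "importance"], abs=1e-12
        )


def test_dominant_predictor_gets_high_importance(rng):
    cells = make_cells(10, 10)
    y, X, W = sar_error_data(rng, cells, rho=0.4, beta=[1.5, 0.0, 0.0], sigma=0.5)
    Xdf = pd.DataFrame(X, columns=["signal", "junk1", "junk2"])
    avg = multimodel_average(standardize(y), Xdf, W)
    assert avg.coefficients.loc["signal", "importance"] > 0.95
    assert avg.coefficients.loc["signal", "coef"] > 0


# ------------------------------------------------- corrected t and piecewise


def test_modified_t_structural_properties(rng):
    cells = make_cells(8, 8)
    a = rng.standard_normal(64)
    res = modified_t_test(a, a, cells)
    assert res.r == pytest.approx(1.0)
    b = rng.standard_normal(64)
    res = modified_t_test(a, b, cells)
    assert res.r == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)
    assert 3.0 <= res.n_eff <= 64
    # iid fields keep most of the sample size
    assert res.n_eff > 0.5 * 64


def test_piecewise_fits():
    lat = np.linspace(0, 60, 80)
    y = 2.0 + 0.3 * lat
    fit = piecewise_latitudinal_fit(y, lat)
    assert fit.slope_below == pytest.approx(0.3, abs=1e-6)
    assert fit.slope_above == pytest.approx(0.3, abs=1e-6)

    hinge = 2.0 + 0.1 * lat + 0.5 * np.maximum(lat - 30.0, 0)
    fit = piecewise_latitudinal_fit(hinge, lat)
    assert abs(fit.breakpoint - 30.0) < 2.0
    assert fit.slope_below == pytest.approx(0.1, abs=0.02)
    assert fit.slope_above == pytest.approx(0.6, abs=0.02)


def test_piecewise_never_beats_itself(rng):
    lat = np.linspace(-30, 30, 50)
    y = rng.standard_normal(50)
    fit = piecewise_latitudinal_fit(y, lat)
    assert fit.sse <= fit.sse_linear + 1e-9
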