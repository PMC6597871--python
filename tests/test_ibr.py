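"""MLPE/NMLPE mixed models, model selection and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from landgen.ibr import (
    all_subsets_selection, build_pair_table, fit_mlpe, likelihood_ratio_test,
    residual_serial_autocorrelation, simulate_mlpe_dataset, subset_sensitivity,
)
from landgen.relatedness import RelatednessMatrix


def _samples(n_loc, col):
    n = n_loc * col
    rng = np.random.default_rng(0)
    lon = np.repeat(rng.uniform(-45, -40, n_loc), col)
    lat = np.repeat(rng.uniform(-8, -3, n_loc), col)
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)], "lon": lon, "lat": lat,
        "location_id": np.repeat([f"L{k}" for k in range(n_loc)], col),
    })


def _rel(n, rng):
    a = rng.normal(0, 0.05, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return RelatednessMatrix(a, np.full((n, n), 50.0), [f"s{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# Pair table assembly

def test_pair_table_shape_and_standardization(rng):
    samples = _samples(4, 1)
    rel = _rel(4, rng)
    d = {"x": rng.uniform(0, 5, (4, 4))}
    d["x"] = (d["x"] + d["x"].T) / 2
    np.fill_diagonal(d["x"], 0)
    pt = build_pair_table(rel, d, samples)
    assert pt.n_pairs == 6
    col = pt.data["x"].to_numpy()
    assert abs(col.mean()) < 1e-12
    assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-12)


def test_pair_table_location_pair_key_symmetric(rng):
    samples = _samples(2, 2)  # two samples per location
    rel = _rel(4, rng)
    d = np.abs(rng.normal(1, 0.1, (4, 4)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    pt = build_pair_table(rel, {"x": d}, samples)
    within = pt.data[pt.data["loc_i"] == pt.data["loc_j"]]
    assert (within["loc_pair"].apply(lambda t: t[0] == t[1])).all()


def test_pair_table_drops_infinite_distances(rng):
    samples = _samples(4, 1)
    rel = _rel(4, rng)
    d = np.ones((4, 4))
    np.fill_diagonal(d, 0)
    d[0, 1] = d[1, 0] = np.inf
    d[0, 2], d[2, 0] = 2.0, 2.0
    with pytest.warns(UserWarning, match="infinite"):
        pt = build_pair_table(rel, {"x": d}, samples)
    assert pt.n_pairs == 5


# ---------------------------------------------------------------------------
# Fitting

def test_zero_variance_boundary_fit_equals_ols():
    # scan null datasets for one where the variance ratio is estimated on
    # the boundary; there the profiled GLS collapses to OLS exactly
    found = False
    for seed in range(10):
        pt = simulate_mlpe_dataset(10, 2, beta=-0.5, sigma_u=0.0, sigma_e=1.0,
                                   predictor_level="pair", seed=seed)
        fit = fit_mlpe(pt, ["x"])
        X = np.column_stack([np.ones(pt.n_pairs), pt.data["x"]])
        y = pt.data["response"].to_numpy()
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        if fit.sigma2_u == 0.0:
            found = True
            np.testing.assert_allclose(fit.beta, b_ols, atol=1e-10)
        else:
            np.testing.assert_allclose(fit.beta, b_ols, atol=0.02)
    assert found


def test_parameter_recovery_beta_and_rho():
    # rho = 0.3 corresponds to sigma_u^2/sigma_e^2 = 0.75
    covered = 0
    rhos = []
    for seed in range(20):
        pt = simulate_mlpe_dataset(20, 3, beta=-0.5, sigma_u=np.sqrt(0.75),
                                   sigma_e=1.0, predictor_level="pair", seed=seed)
        fit = fit_mlpe(pt, ["x"])
        covered += abs(fit.beta[1] + 0.5) < 2 * fit.se[1]
        rhos.append(fit.rho)
    assert covered >= 17
    assert np.mean(rhos) == pytest.approx(0.3, abs=0.05)


def test_nesting_likelihood_monotone(rng):
    pt = simulate_mlpe_dataset(10, 3, beta=-0.3, sigma_u=0.3, sigma_v=0.3,
                               seed=3)
    full = fit_mlpe(pt, ["x"], nested=True)
    null = fit_mlpe(pt, [], nested=True)
    assert full.loglik >= null.loglik - 1e-8
    mlpe = fit_mlpe(pt, ["x"], nested=False)
    assert full.loglik >= mlpe.loglik - 1e-6  # NMLPE nests MLPE


def test_rho_bounded_and_aic_identity(rng):
    pt = simulate_mlpe_dataset(8, 3, beta=0.2, sigma_u=0.5, sigma_v=0.2, seed=1)
    for nested in (False, True):
        fit = fit_mlpe(pt, ["x"], nested=nested)
        assert 0.0 <= fit.rho <= 0.5
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)


def test_single_colony_identifiability_flagged():
    pt = simulate_mlpe_dataset(12, 1, beta=0.0, sigma_u=0.3, seed=0)
    with pytest.warns(UserWarning, match="identifiable"):
        fit = fit_mlpe(pt, ["x"], nested=True)
    assert not fit.identifiable


def test_singular_design_errors():
    pt = simulate_mlpe_dataset(8, 2, beta=0.1, seed=0)
    pt.data["x2"] = pt.data["x"]
    pt.predictors.append("x2")
    with pytest.raises(ValueError, match="singular"):
        fit_mlpe(pt, ["x", "x2"])


def test_reml_refuses_lrt():
    pt = simulate_mlpe_dataset(8, 2, beta=0.1, seed=0)
    a = fit_mlpe(pt, ["x"], method="reml")
    b = fit_mlpe(pt, [], method="reml")
    with pytest.raises(ValueError, match="ML"):
        likelihood_ratio_test(a, b)


# ---------------------------------------------------------------------------
# LRT

def test_lrt_identical_models_chi2_zero():
    pt = simulate_mlpe_dataset(8, 2, beta=0.1, seed=0)
    fit = fit_mlpe(pt, ["x"])
    chi2, df, p = likelihood_ratio_test(fit, fit)
    assert chi2 == 0.0 and df == 0 and p == 1.0


def test_lrt_strong_predictor_significant():
    hits = 0
    for seed in range(10):
        pt = simulate_mlpe_dataset(15, 3, beta=-0.5, sigma_u=0.3, seed=seed)
        full = fit_mlpe(pt, ["x"])
        red = fit_mlpe(pt, [])
        _, _, p = likelihood_ratio_test(full, red)
        hits += p < 0.001
    assert hits >= 9


def test_lrt_null_type_one_error_calibrated():
    # correctly specified correlation structure: rejection ~ alpha
    rejections = 0
    n_rep = 60
    for seed in range(n_rep):
        pt = simulate_mlpe_dataset(12, 3, beta=0.0, sigma_u=0.4, sigma_v=0.0,
                                   predictor_level="pair", seed=seed)
        full = fit_mlpe(pt, ["x"])
        red = fit_mlpe(pt, [])
        _, _, p = likelihood_ratio_test(full, red)
        rejections += p < 0.05
    assert rejections / n_rep < 0.15


# ---------------------------------------------------------------------------
# Residual diagnostics (the NMLPE motivation)

def test_serial_autocorrelation_contrast():
    # location-pair noise fitted by plain MLPE leaves positive lag-1
    # autocorrelation in location-sorted whitened residuals; NMLPE removes it
    mlpe_acs, nmlpe_acs = [], []
    for seed in range(5):
        pt = simulate_mlpe_dataset(15, 3, beta=0.0, sigma_u=0.3, sigma_v=0.8,
                                   sigma_e=0.4, seed=seed)
        m = fit_mlpe(pt, ["x"], nested=False)
        nm = fit_mlpe(pt, ["x"], nested=True)
        mlpe_acs.append(residual_serial_autocorrelation(m, pt))
        nmlpe_acs.append(residual_serial_autocorrelation(nm, pt))
    assert np.mean(mlpe_acs) > 0.1
    assert abs(np.mean(nmlpe_acs)) < 0.05


def test_white_noise_residuals_uncorrelated():
    pt = simulate_mlpe_dataset(15, 2, beta=0.0, sigma_u=0.0, sigma_v=0.0,
                               sigma_e=1.0, seed=4)
    fit = fit_mlpe(pt, ["x"])
    assert abs(residual_serial_autocorrelation(fit, pt)) < 0.1


# ---------------------------------------------------------------------------
# Model selection

def test_collinear_predictors_never_cooccur(rng):
    pt = simulate_mlpe_dataset(10, 2, beta=-0.5, sigma_u=0.3, seed=2)
    pt.data["x_twin"] = pt.data["x"] * 0.97 + rng.normal(0, 0.1, pt.n_pairs)
    pt.predictors.append("x_twin")
    r = np.corrcoef(pt.data["x"], pt.data["x_twin"])[0, 1]
    assert abs(r) > 0.9
    table = all_subsets_selection(pt, ["x", "x_twin"], collinearity_rmax=0.6)
    for terms in table["predictors"]:
        assert not ("x" in terms.split(" + ") and "x_twin" in terms.split(" + "))


def test_selection_table_invariants():
    pt = simulate_mlpe_dataset(10, 2, beta=-0.5, sigma_u=0.3, seed=2)
    table = all_subsets_selection(pt, ["x"])
    assert table["delta_aic"].iloc[0] == 0.0
    assert (table["delta_aic"] >= 0).all()
    assert table["weight"].sum() == pytest.approx(1.0)
    # AIC reproducible from loglik and parameter count
    np.testing.assert_allclose(table["aic"], -2 * table["loglik"] + 2 * table["k"])


def test_true_predictor_selected():
    hits = 0
    for seed in range(10):
        pt = simulate_mlpe_dataset(20, 3, beta=-0.5, sigma_u=0.3, seed=seed)
        table = all_subsets_selection(pt, ["x"])
        hits += table.iloc[0]["predictors"] == "x"
    assert hits >= 9


# ---------------------------------------------------------------------------
# Subset sensitivity

def test_subset_sensitivity_deterministic_and_strong_predictor():
    pt = simulate_mlpe_dataset(12, 2, beta=-0.8, sigma_u=0.2, seed=1)
    t1 = subset_sensitivity(pt, ["x"], n_subsets=8, exclusion_sizes=(0, 2), seed=9)
    t2 = subset_sensitivity(pt, ["x"], n_subsets=8, exclusion_sizes=(0, 2), seed=9)
    pd.testing.assert_frame_equal(t1, t2)
    freqs = t1.set_index("exclusion_size")["inclusion_freq"]
    assert freqs.loc[0] in (0.0, 1.0)  # no exclusion: identical subsets
    assert freqs.loc[2] >= 0.9
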