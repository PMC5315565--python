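"""CFA estimation, fit indices and factor scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methrisk.cfa import (FactorModelFit, FactorModelSpec, factor_scores,
                          fit_cfa, rmsea, rmsea_ci)
from methrisk.simulate import SUBSTANCE_ITEMS, SimConfig, simulate_cohort


def _implied_sigma(first, second, psi=None, theta=None):
    """Population covariance of the 8 indicators for standardized loadings."""
    first = np.asarray(first)
    second = np.asarray(second)
    lam = np.zeros((8, 3))
    fidx = [0, 0, 0, 1, 1, 1, 2, 2]
    for i, k in enumerate(fidx):
        lam[i, k] = first[i]
    psi = np.asarray(psi) if psi is not None else 1 - second ** 2
    theta = np.asarray(theta) if theta is not None else 1 - first ** 2
    fcov = np.outer(second, second) + np.diag(psi)
    return lam @ fcov @ lam.T + np.diag(theta)


def _data_with_exact_cov(sigma, n, seed=0):
    """n samples whose *sample* covariance equals sigma exactly."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, sigma.shape[0]))
    Z = Z - Z.mean(axis=0)
    S = np.cov(Z, rowvar=False, ddof=1)
    W = np.linalg.cholesky(np.linalg.inv(S))
    X = Z @ W @ np.linalg.cholesky(sigma).T
    return pd.DataFrame(X, columns=list(SUBSTANCE_ITEMS))


def test_saturated_fit_at_population_covariance():
    """Data whose sample covariance equals a model-implied covariance must
    fit perfectly: F_ML ~ 0, chi^2 ~ 0, CFI = 1, RMSEA = 0."""
    first = np.array([0.85, 0.9, 0.8, 0.8, 0.9, 0.85, 0.7, 0.75])
    second = np.array([0.9, 0.85, 0.8])
    sigma = _implied_sigma(first, second)
    data = _data_with_exact_cov(sigma, n=500, seed=3)
    fit = fit_cfa(data)
    assert fit.converged
    assert fit.objective < 1e-7
    assert fit.chi_square < 1e-4
    assert fit.cfi == pytest.approx(1.0, abs=1e-6)
    assert fit.rmsea == pytest.approx(0.0, abs=1e-6)
    # standardized loadings recover the generating values
    np.testing.assert_allclose(
        fit.loadings_std["loading"].to_numpy(), first, atol=1e-4)
    np.testing.assert_allclose(
        fit.second_order_loadings_std.to_numpy(), second, atol=1e-4)


def test_rmsea_point_formula_reproduces_published_value():
    """chi^2 = 49.55, df = 18, N = 244 must give RMSEA that prints as 0.08,
    whether the N or N-1 convention is used."""
    assert round(rmsea(49.55, 18, 244), 2) == 0.08
    assert round(np.sqrt((49.55 - 18) / (18 * 244)), 2) == 0.08


def _oracle_noncentrality(x, df, target, tol=1e-10):
    """Independent bisection inversion of the noncentral chi-square CDF."""
    def cdf(nc):
        return stats.chi2.cdf(x, df) if nc == 0 else stats.ncx2.cdf(x, df, nc)
    if cdf(0.0) < target:
        return 0.0
    lo, hi = 0.0, 10.0
    while cdf(hi) > target:
        hi *= 2
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if cdf(mid) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def test_rmsea_ci_matches_inversion_oracle():
    chi2, df, N = 49.55, 18, 244
    lo, hi = rmsea_ci(chi2, df, N)
    nc_lo = _oracle_noncentrality(chi2, df, 0.95)
    nc_hi = _oracle_noncentrality(chi2, df, 0.05)
    assert lo == pytest.approx(np.sqrt(nc_lo / (df * (N - 1))), abs=1e-6)
    assert hi == pytest.approx(np.sqrt(nc_hi / (df * (N - 1))), abs=1e-6)
    assert lo <= hi


def test_rmsea_ci_degenerate_cases():
    # chi2 == df: observed fit at the null expectation -> lower bound 0
    lo, _ = rmsea_ci(18.0, 18, 244)
    assert lo == 0.0
    # level 0 -> both bounds solve the same median equation
    lo0, hi0 = rmsea_ci(49.55, 18, 244, level=0.0)
    assert lo0 == pytest.approx(hi0, abs=1e-9)
    with pytest.raises(ValueError):
        rmsea_ci(-1.0, 18, 244)


def test_loading_recovery_on_simulated_cohort():
    cfg = SimConfig(n_samples=2000, n_probes=300, n_dmps=5, n_mqtl_dmps=1,
                    n_panel_probes=40, n_sex_probes=5, exposure_effects={},
                    seed=3)
    _, _, cohort, truth, _, _ = simulate_cohort(cfg)
    fit = fit_cfa(cohort)
    assert fit.converged and fit.admissible
    dev_first = np.abs(fit.loadings_std["loading"].to_numpy()
                       - np.array(truth.factor_loadings_first))
    dev_second = np.abs(fit.second_order_loadings_std.to_numpy()
                        - np.array(truth.factor_loadings_second))
    assert dev_first.max() < 0.05
    assert dev_second.max() < 0.05
    # regression factor score tracks the true liability closely
    score = fit.factor_score_table["substance_use"]
    assert np.corrcoef(score, truth.liability)[0, 1] > 0.9
    assert score.mean() == pytest.approx(0.0, abs=1e-9)
    assert score.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_chi_square_invariant_to_sample_order():
    cfg = SimConfig(n_samples=400, n_probes=100, n_dmps=2, n_mqtl_dmps=0,
                    n_panel_probes=20, n_sex_probes=2, exposure_effects={},
                    seed=8)
    _, _, cohort, _, _, _ = simulate_cohort(cfg)
    fit1 = fit_cfa(cohort, compute_scores=False)
    shuffled = cohort.sample(frac=1.0, random_state=1)
    fit2 = fit_cfa(shuffled, compute_scores=False)
    assert fit1.chi_square == pytest.approx(fit2.chi_square, rel=1e-6)
    assert fit1.cfi == pytest.approx(fit2.cfi, rel=1e-6)


def _handmade_fit(loadings=1.0, theta=1e-12):
    spec = FactorModelSpec()
    items = spec.indicator_names
    names = spec.factor_names
    return FactorModelFit(
        spec=spec,
        loadings=pd.DataFrame({"factor": [names[k] for k in spec.factor_index()],
                               "loading": [loadings] * 8},
                              index=pd.Index(items, name="indicator")),
        loadings_std=pd.DataFrame({"factor": [names[k] for k in spec.factor_index()],
                                   "loading": [loadings] * 8},
                                  index=pd.Index(items, name="indicator")),
        second_order_loadings=pd.Series([1.0, 1.0, 1.0], index=names),
        second_order_loadings_std=pd.Series([1.0, 1.0, 1.0], index=names),
        residual_variances=pd.Series([theta] * 8, index=items),
        disturbances=pd.Series([theta] * 3, index=names),
        phi=1.0, chi_square=0.0, df=17, p_chi=1.0, cfi=1.0, tli=1.0,
        rmsea=0.0, rmsea_ci90=(0.0, 0.0), n=100, converged=True,
        admissible=True, objective=0.0)


def test_factor_scores_deterministic_limit():
    """With unit loadings and vanishing unique variances the liability score
    equals the standardized per-sample indicator mean."""
    rng = np.random.default_rng(0)
    L = rng.standard_normal(200)
    data = pd.DataFrame({item: L for item in SUBSTANCE_ITEMS})
    scores = factor_scores(_handmade_fit(), data)
    expected = (L - L.mean()) / L.std(ddof=1)
    np.testing.assert_allclose(scores["substance_use"], expected, atol=1e-6)


def test_factor_scores_permutation_equivariance():
    rng = np.random.default_rng(4)
    data = pd.DataFrame(rng.standard_normal((60, 8)),
                        columns=list(SUBSTANCE_ITEMS))
    fit = _handmade_fit(loadings=0.8, theta=0.36)
    s1 = factor_scores(fit, data)
    perm = rng.permutation(60)
    s2 = factor_scores(fit, data.iloc[perm])
    np.testing.assert_allclose(s1.iloc[perm].to_numpy(), s2.to_numpy(),
                               atol=1e-10)


def test_nonconverged_fit_refuses_to_score():
    fit = _handmade_fit()
    fit.converged = False
    with pytest.raises(ValueError):
        factor_scores(fit, pd.DataFrame(np.zeros((5, 8)),
                                        columns=list(SUBSTANCE_ITEMS)))
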