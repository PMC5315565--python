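"""Confirmatory factor analysis of adolescent substance use.

The measurement model has three first-order factors — tobacco, cannabis and
alcohol use, each measured by repeated assessments across ages 14-18 — and
a single second-order "substance-use liability" factor capturing the shared
variance between substances and across time. The model is estimated by
normal-theory maximum likelihood: minimize

    F_ML(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

over the free parameters, with chi^2 = (N - 1) F_ML at the optimum.
Identification fixes the first loading of every factor (including the
second-order factor) to 1. Ordinal frequency items are treated as
continuous indicators, the usual default for ML estimation.

Fit is summarized by chi^2, CFI, TLI and RMSEA with a 90% CI obtained by
inverting the noncentral chi-square CDF. Factor scores use the regression
(Thurstone) method; the second-order score — the EWAS outcome — is returned
standardized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["FactorModelSpec", "FactorModelFit", "fit_cfa", "rmsea",
           "rmsea_ci", "factor_scores"]


@dataclass
class FactorModelSpec:
    """Indicator -> first-order factor structure, plus a second-order factor.

    Every indicator loads on exactly one first-order factor; the first
    indicator listed per factor is the marker (loading fixed to 1), and the
    first first-order factor is the marker of the second-order factor.
    """

    factors: dict[str, list[str]] = field(default_factory=lambda: {
        "tobacco": ["tobacco_14", "tobacco_16", "tobacco_18"],
        "cannabis": ["cannabis_14", "cannabis_16", "cannabis_18"],
        "alcohol": ["alcohol_16", "alcohol_18"],
    })
    second_order: str = "substance_use"

    @property
    def indicator_names(self) -> list[str]:
        return [i for items in self.factors.values() for i in items]

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    def factor_index(self) -> np.ndarray:
        """Factor index per indicator, in indicator order."""
        idx = []
        for k, items in enumerate(self.factors.values()):
            idx.extend([k] * len(items))
        return np.array(idx)

    def n_free_parameters(self) -> int:
        p = len(self.indicator_names)
        q = len(self.factors)
        free_lambda = p - q          # markers fixed
        free_gamma = q - 1           # second-order marker fixed
        return free_lambda + free_gamma + 1 + q + p  # + phi + psi + theta

    def degrees_of_freedom(self) -> int:
        p = len(self.indicator_names)
        return p * (p + 1) // 2 - self.n_free_parameters()


@dataclass
class FactorModelFit:
    spec: FactorModelSpec
    loadings: pd.DataFrame            # unstandardized, indicator x [factor, loading]
    loadings_std: pd.DataFrame
    second_order_loadings: pd.Series  # unstandardized, per first-order factor
    second_order_loadings_std: pd.Series
    residual_variances: pd.Series
    disturbances: pd.Series
    phi: float                        # second-order factor variance
    chi_square: float
    df: int
    p_chi: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    n: int
    converged: bool
    admissible: bool
    objective: float
    factor_score_table: pd.DataFrame | None = None

    def summary(self) -> dict:
        return {
            "chi_square": self.chi_square, "df": self.df, "p_chi": self.p_chi,
            "cfi": self.cfi, "tli": self.tli, "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90), "n": self.n,
            "converged": self.converged, "admissible": self.admissible,
            "loadings_std": self.loadings_std["loading"].to_dict(),
            "second_order_loadings_std": self.second_order_loadings_std.to_dict(),
        }


def _unpack(theta: np.ndarray, spec: FactorModelSpec):
    p = len(spec.indicator_names)
    q = len(spec.factors)
    fidx = spec.factor_index()
    pos = 0
    lam = np.zeros((p, q))
    seen = set()
    for i in range(p):
        k = fidx[i]
        if k not in seen:
            lam[i, k] = 1.0
            seen.add(k)
        else:
            lam[i, k] = theta[pos]; pos += 1
    gamma = np.empty(q)
    gamma[0] = 1.0
    gamma[1:] = theta[pos:pos + q - 1]; pos += q - 1
    phi = theta[pos]; pos += 1
    psi = theta[pos:pos + q]; pos += q
    theta_eps = theta[pos:pos + p]; pos += p
    return lam, gamma, phi, psi, theta_eps


def _implied(lam, gamma, phi, psi, theta_eps) -> np.ndarray:
    factor_cov = phi * np.outer(gamma, gamma) + np.diag(psi)
    return lam @ factor_cov @ lam.T + np.diag(theta_eps)


def _fml(sigma: np.ndarray, S: np.ndarray, logdet_S: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    try:
        solve = np.linalg.solve(sigma, S)
    except np.linalg.LinAlgError:
        return np.inf
    return logdet + np.trace(solve) - logdet_S - S.shape[0]


def fit_cfa(data: pd.DataFrame, spec: FactorModelSpec | None = None,
            n_override: int | None = None,
            compute_scores: bool = True) -> FactorModelFit:
    """Fit the second-order CFA by maximum likelihood.

    ``data`` holds one column per indicator (extra columns ignored); rows
    with any missing indicator are dropped (complete-case). ``n_override``
    lets callers fit a covariance matrix supplied as pseudo-data with a
    different nominal N.
    """
    spec = spec or FactorModelSpec()
    items = spec.indicator_names
    X = data[items].dropna().to_numpy(dtype=float)
    N = n_override if n_override is not None else X.shape[0]
    p = len(items)
    q = len(spec.factors)
    if X.shape[0] <= spec.n_free_parameters():
        raise ValueError("more free parameters than observations")
    S = np.cov(X, rowvar=False, ddof=1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0 or not np.isfinite(logdet_S):
        raise ValueError("sample covariance matrix is singular")

    fidx = spec.factor_index()
    var_diag = np.diag(S)

    def objective(theta):
        return _fml(_implied(*_unpack(theta, spec)), S, logdet_S)

    # start values: unit loadings, half the indicator variance to residuals
    def start(jitter_rng=None):
        lam0 = np.ones(p - q)
        gam0 = np.ones(q - 1)
        phi0 = np.array([0.5 * var_diag.mean()])
        psi0 = np.full(q, 0.25 * var_diag.mean())
        th0 = 0.5 * var_diag
        x0 = np.concatenate([lam0, gam0, phi0, psi0, th0])
        if jitter_rng is not None:
            x0 = x0 * jitter_rng.uniform(0.5, 1.5, size=x0.size)
        return x0

    n_load = (p - q) + (q - 1)
    bounds = [(None, None)] * n_load + [(1e-8, None)] * (1 + q + p)

    best = None
    rng = np.random.default_rng(12345)
    for attempt in range(4):
        x0 = start(None if attempt == 0 else rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 5000, "ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.success and np.isfinite(best.fun):
            break
    res = best
    converged = bool(res.success and np.isfinite(res.fun))
    lam, gamma, phi, psi, theta_eps = _unpack(res.x, spec)

    fml = max(res.fun, 0.0)
    chi2 = (N - 1) * fml
    df = spec.degrees_of_freedom()
    p_chi = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan

    # independence baseline
    f0 = float(np.sum(np.log(var_diag)) - logdet_S)
    chi0 = (N - 1) * f0
    df0 = p * (p - 1) // 2
    cfi_num = max(chi2 - df, 0.0)
    cfi_den = max(chi0 - df0, chi2 - df, 0.0)
    cfi = 1.0 - (cfi_num / cfi_den if cfi_den > 0 else 0.0)
    ratio0 = chi0 / df0
    ratio_m = chi2 / df if df > 0 else np.nan
    tli = (ratio0 - ratio_m) / (ratio0 - 1.0) if ratio0 != 1.0 else np.nan
    rmsea_pt = rmsea(chi2, df, N)
    ci = rmsea_ci(chi2, df, N)

    factor_cov = phi * np.outer(gamma, gamma) + np.diag(psi)
    fvar = np.diag(factor_cov)
    sigma = _implied(lam, gamma, phi, psi, theta_eps)
    ivar = np.diag(sigma)
    lam_std = lam * np.sqrt(fvar)[None, :] / np.sqrt(ivar)[:, None]
    gamma_std = gamma * np.sqrt(phi) / np.sqrt(fvar)

    factor_names = spec.factor_names
    loadings = pd.DataFrame({
        "factor": [factor_names[k] for k in fidx],
        "loading": [lam[i, fidx[i]] for i in range(p)],
    }, index=pd.Index(items, name="indicator"))
    loadings_std = loadings.copy()
    loadings_std["loading"] = [lam_std[i, fidx[i]] for i in range(p)]

    admissible = bool(
        converged
        and np.all(np.abs(loadings_std["loading"]) <= 1 + 1e-6)
        and np.all(np.abs(gamma_std) <= 1 + 1e-6)
        and np.all(theta_eps > 1e-7) and np.all(psi > 1e-7) and phi > 1e-7)

    fit = FactorModelFit(
        spec=spec,
        loadings=loadings, loadings_std=loadings_std,
        second_order_loadings=pd.Series(gamma, index=factor_names),
        second_order_loadings_std=pd.Series(gamma_std, index=factor_names),
        residual_variances=pd.Series(theta_eps, index=items),
        disturbances=pd.Series(psi, index=factor_names),
        phi=float(phi),
        chi_square=float(chi2), df=df, p_chi=p_chi,
        cfi=float(cfi), tli=float(tli), rmsea=float(rmsea_pt),
        rmsea_ci90=ci, n=int(N), converged=converged, admissible=admissible,
        objective=float(fml),
    )
    if compute_scores and converged:
        fit.factor_score_table = factor_scores(fit, data)
    return fit


def rmsea(chi_square: float, df: int, n: int) -> float:
    """Point RMSEA, sqrt(max(chi^2 - df, 0) / (df (N - 1)))."""
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))


def _ncx2_cdf(x: float, df: int, nc: float) -> float:
    if nc <= 0:
        return float(stats.chi2.cdf(x, df))
    return float(stats.ncx2.cdf(x, df, nc))


def _solve_noncentrality(x: float, df: int, target: float) -> float:
    """Largest-bracket solve of P(chi2_df(nc) <= x) = target for nc >= 0."""
    if _ncx2_cdf(x, df, 0.0) < target:
        return 0.0
    hi = max(2.0 * x, 10.0)
    for _ in range(200):
        if _ncx2_cdf(x, df, hi) < target:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket noncentrality root")
    return float(optimize.brentq(
        lambda nc: _ncx2_cdf(x, df, nc) - target, 0.0, hi, xtol=1e-12))


def rmsea_ci(chi_square: float, df: int, n: int,
             level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-based RMSEA confidence interval.

    The bounds invert the noncentral chi-square CDF: the lower bound uses
    the noncentrality at which the observed chi-square sits at the upper
    (1+level)/2 quantile, the upper bound the lower quantile; each bound is
    sqrt(nc / (df (N - 1))), clipped at 0.
    """
    if chi_square < 0 or df < 1 or n < 2:
        raise ValueError("need chi_square >= 0, df >= 1, N >= 2")
    alpha = (1.0 - level) / 2.0
    nc_lo = _solve_noncentrality(chi_square, df, 1.0 - alpha)
    nc_hi = _solve_noncentrality(chi_square, df, alpha)
    denom = df * (n - 1)
    lo = float(np.sqrt(max(nc_lo, 0.0) / denom))
    hi = float(np.sqrt(max(nc_hi, 0.0) / denom))
    return (lo, hi)


def factor_scores(fit: FactorModelFit, data: pd.DataFrame,
                  method: str = "regression") -> pd.DataFrame:
    """Regression (Thurstone) factor scores from a converged fit.

    Returns one column per first-order factor plus the second-order score
    (column named after ``spec.second_order``), which is standardized to
    mean 0, SD 1. Scores are linear in the centered indicators; a
    pseudo-inverse is used so deterministic (singular-Sigma) models still
    score.
    """
    if method != "regression":
        raise ValueError(f"unknown scoring method: {method}")
    if not fit.converged:
        raise ValueError("cannot score a non-converged fit")
    spec = fit.spec
    items = spec.indicator_names
    Y = data[items].dropna()
    yc = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=0)

    p = len(items)
    q = len(spec.factors)
    fidx = spec.factor_index()
    lam = np.zeros((p, q))
    for i in range(p):
        lam[i, fidx[i]] = fit.loadings["loading"].iloc[i]
    gamma = fit.second_order_loadings.to_numpy()
    psi = fit.disturbances.to_numpy()
    theta_eps = fit.residual_variances.to_numpy()
    phi = fit.phi

    factor_cov = phi * np.outer(gamma, gamma) + np.diag(psi)
    sigma = lam @ factor_cov @ lam.T + np.diag(theta_eps)
    cov_first = factor_cov @ lam.T                    # q x p
    cov_second = phi * gamma @ lam.T                  # p,
    sigma_pinv = np.linalg.pinv(sigma, rcond=1e-10)

    first = yc @ sigma_pinv @ cov_first.T
    second = yc @ sigma_pinv @ cov_second
    sd = second.std(ddof=1)
    if sd > 0:
        second = (second - second.mean()) / sd

    out = pd.DataFrame(first, columns=spec.factor_names, index=Y.index)
    out[spec.second_order] = second
    return out
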