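"""Path-analytic mediation: prenatal exposures -> DNAm risk -> substance use.

The model is a recursive linear path model, estimated by ML — equivalently,
two OLS regressions: the mediator on the exposures (a-paths) and the
outcome on the mediator plus exposures (b-path and direct c'-paths). Each
exposure's indirect effect is the product ``a_k * b``, with inference by
nonparametric case-resampling bootstrap (percentile CIs by default,
bias-corrected behind a flag), alongside Wald p-values. The mediator and
outcome are z-scored by default so coefficients are comparable across runs;
unstandardized estimates on the supplied scale are what the coefficients
then are.

Utilities: per-substance variants of the model (the three first-order
factor scores as outcomes) and winsorization at mean +- k SD for outlier
sensitivity reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MediationFit", "fit_path_model", "bootstrap_ci",
           "per_substance_mediation", "winsorize"]


@dataclass
class MediationFit:
    exposure_names: list[str]
    a: pd.Series                 # exposure -> mediator
    a_se: pd.Series
    b: float                     # mediator -> outcome
    b_se: float
    c_prime: pd.Series           # direct exposure -> outcome
    c_prime_se: pd.Series
    indirect: pd.Series          # a_k * b
    a_std: pd.Series
    b_std: float
    c_prime_std: pd.Series
    indirect_std: pd.Series
    n: int
    p_values: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)  # filled by bootstrap_ci
    outcome_name: str = "outcome"

    def summary(self) -> dict:
        out = {
            "n": self.n,
            "outcome": self.outcome_name,
            "b": self.b, "b_se": self.b_se,
            "a": self.a.to_dict(), "a_se": self.a_se.to_dict(),
            "c_prime": self.c_prime.to_dict(),
            "indirect": self.indirect.to_dict(),
            "indirect_std": self.indirect_std.to_dict(),
            "p_values": self.p_values,
        }
        if self.bootstrap:
            out["bootstrap"] = {
                k: v for k, v in self.bootstrap.items() if k != "replicates"}
        return out


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and SEs of OLS with intercept prepended."""
    n = X.shape[0]
    Z = np.column_stack([np.ones(n), X])
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    coef = ZtZ_inv @ (Z.T @ y)
    resid = y - Z @ coef
    dof = n - Z.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(ZtZ_inv))
    return coef, se


def _prepare(exposures: pd.DataFrame, mediator: pd.Series, outcome: pd.Series,
             standardize: bool):
    data = pd.concat([exposures,
                      mediator.rename("_m"), outcome.rename("_y")], axis=1)
    data = data.dropna()
    X = data[exposures.columns].to_numpy(dtype=float)
    m = data["_m"].to_numpy(dtype=float)
    y = data["_y"].to_numpy(dtype=float)
    if standardize:
        m = (m - m.mean()) / m.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    return X, m, y, data.index


def _condition_guard(X: np.ndarray) -> None:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant exposure column")
    cond = np.linalg.cond(np.corrcoef(Xc, rowvar=False)) if X.shape[1] > 1 else 1.0
    if cond > 1e8:
        raise ValueError(f"exposures are collinear (condition number {cond:.2g})")


def _fit_arrays(X: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Point estimates from raw arrays; returns (a, b, c') and SEs."""
    coef_m, se_m = _ols(X, m)
    Xy = np.column_stack([m, X])
    coef_y, se_y = _ols(Xy, y)
    a, a_se = coef_m[1:], se_m[1:]
    b, b_se = coef_y[1], se_y[1]
    c, c_se = coef_y[2:], se_y[2:]
    return a, a_se, b, b_se, c, c_se


def fit_path_model(exposures: pd.DataFrame, mediator: pd.Series,
                   outcome: pd.Series, standardize: bool = True,
                   outcome_name: str = "outcome") -> MediationFit:
    """Point estimates of the recursive path model on complete cases.

    ``standardize`` z-scores the mediator and outcome before fitting (the
    default, so path coefficients are comparable across scores built on
    different probe sets); exposures always enter on their original scale.
    Standardized coefficients (all variables scaled) are reported alongside.
    """
    X, m, y, index = _prepare(exposures, mediator, outcome, standardize)
    n, k = X.shape
    if n <= 2 * k + 3:
        raise ValueError("too few complete cases for the path model")
    _condition_guard(X)
    a, a_se, b, b_se, c, c_se = _fit_arrays(X, m, y)

    names = list(exposures.columns)
    sd_x = X.std(axis=0, ddof=1)
    sd_m = m.std(ddof=1)
    sd_y = y.std(ddof=1)
    a_std = a * sd_x / sd_m
    b_std = b * sd_m / sd_y
    c_std = c * sd_x / sd_y

    dof_m = n - k - 1
    dof_y = n - k - 2
    p_vals = {
        "a": {nm: float(2 * stats.t.sf(abs(av / se), dof_m))
              for nm, av, se in zip(names, a, a_se)},
        "b": float(2 * stats.t.sf(abs(b / b_se), dof_y)),
        "c_prime": {nm: float(2 * stats.t.sf(abs(cv / se), dof_y))
                    for nm, cv, se in zip(names, c, c_se)},
    }
    # Sobel-style Wald p for the indirect effects
    ind = a * b
    ind_se = np.sqrt(b ** 2 * a_se ** 2 + a ** 2 * b_se ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_ind = 2 * stats.norm.sf(np.abs(np.where(ind_se > 0, ind / ind_se, 0.0)))
    p_vals["indirect"] = {nm: float(pv) for nm, pv in zip(names, p_ind)}

    return MediationFit(
        exposure_names=names,
        a=pd.Series(a, index=names), a_se=pd.Series(a_se, index=names),
        b=float(b), b_se=float(b_se),
        c_prime=pd.Series(c, index=names), c_prime_se=pd.Series(c_se, index=names),
        indirect=pd.Series(ind, index=names),
        a_std=pd.Series(a_std, index=names), b_std=float(b_std),
        c_prime_std=pd.Series(c_std, index=names),
        indirect_std=pd.Series(a_std * b_std, index=names),
        n=n, p_values=p_vals, outcome_name=outcome_name,
    )


def bootstrap_ci(exposures: pd.DataFrame, mediator: pd.Series,
                 outcome: pd.Series, B: int = 10_000, level: float = 0.95,
                 seed: int = 0, standardize: bool = True,
                 method: str = "percentile",
                 fit: MediationFit | None = None) -> MediationFit:
    """Case-resampling bootstrap CIs for every path and indirect effect.

    Draws ``B`` resamples of the rows (same seed, same CIs, bit for bit),
    refits the two regressions on each, and attaches percentile (or
    bias-corrected) intervals plus replicate summaries to the fit. Singular
    resamples are redrawn and counted.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if method not in ("percentile", "bc"):
        raise ValueError("method must be 'percentile' or 'bc'")
    if fit is None:
        fit = fit_path_model(exposures, mediator, outcome,
                             standardize=standardize)
    X, m, y, _ = _prepare(exposures, mediator, outcome, standardize)
    n, k = X.shape
    rng = np.random.default_rng(seed)

    stats_rows = np.empty((B, 2 * k + 1))  # a_1..a_k, b, c'_1..c'_k
    n_redrawn = 0
    filled = 0
    while filled < B:
        idx = rng.integers(0, n, size=n)
        Xb, mb, yb = X[idx], m[idx], y[idx]
        try:
            if np.any(Xb.std(axis=0) == 0):
                raise np.linalg.LinAlgError
            a, _, b, _, c, _ = _fit_arrays(Xb, mb, yb)
        except np.linalg.LinAlgError:
            n_redrawn += 1
            if n_redrawn > 100 * B:
                raise RuntimeError("bootstrap keeps producing singular fits")
            continue
        stats_rows[filled, :k] = a
        stats_rows[filled, k] = b
        stats_rows[filled, k + 1:] = c
        filled += 1

    names = fit.exposure_names
    alpha = (1 - level) / 2
    a_reps = stats_rows[:, :k]
    b_reps = stats_rows[:, k]
    c_reps = stats_rows[:, k + 1:]
    ind_reps = a_reps * b_reps[:, None]

    def interval(reps: np.ndarray, point: float) -> tuple[float, float]:
        if method == "percentile":
            lo, hi = np.quantile(reps, [alpha, 1 - alpha])
        else:  # bias-corrected
            prop = np.mean(reps < point)
            prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
            z0 = stats.norm.ppf(prop)
            za = stats.norm.ppf(alpha)
            lo_q = stats.norm.cdf(2 * z0 + za)
            hi_q = stats.norm.cdf(2 * z0 - za)
            lo, hi = np.quantile(reps, [lo_q, hi_q])
        return float(lo), float(hi)

    def block(reps2d: np.ndarray, points: np.ndarray) -> dict:
        out = {}
        for j, nm in enumerate(names):
            lo, hi = interval(reps2d[:, j], points[j])
            out[nm] = {"lo": lo, "hi": hi,
                       "boot_mean": float(reps2d[:, j].mean()),
                       "boot_sd": float(reps2d[:, j].std(ddof=1))}
        return out

    b_lo, b_hi = interval(b_reps, fit.b)
    fit.bootstrap = {
        "B": B, "level": level, "seed": seed, "method": method,
        "n_redrawn": n_redrawn,
        "a": block(a_reps, fit.a.to_numpy()),
        "b": {"lo": b_lo, "hi": b_hi, "boot_mean": float(b_reps.mean()),
              "boot_sd": float(b_reps.std(ddof=1))},
        "c_prime": block(c_reps, fit.c_prime.to_numpy()),
        "indirect": block(ind_reps, fit.indirect.to_numpy()),
    }
    return fit


def per_substance_mediation(exposures: pd.DataFrame, mediator: pd.Series,
                            first_order_scores: pd.DataFrame,
                            B: int = 0, seed: int = 0,
                            standardize: bool = True) -> dict[str, MediationFit]:
    """One path model per substance-specific factor score (same exposures
    and mediator). Set ``B > 0`` to attach bootstrap CIs to each."""
    fits = {}
    for col in first_order_scores.columns:
        fit = fit_path_model(exposures, mediator, first_order_scores[col],
                             standardize=standardize, outcome_name=col)
        if B:
            fit = bootstrap_ci(exposures, mediator, first_order_scores[col],
                               B=B, seed=seed, standardize=standardize, fit=fit)
        fits[col] = fit
    return fits


def winsorize(values: pd.Series | np.ndarray, k: float = 3.0
              ) -> tuple[np.ndarray | pd.Series, int]:
    """Replace values beyond mean +- k SD (SD computed before modification)
    by the boundary; returns (winsorized, n_modified)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mu = np.nanmean(arr)
    sd = np.nanstd(arr, ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    lo, hi = mu - k * sd, mu + k * sd
    clipped = np.clip(arr, lo, hi)
    n_modified = int(np.nansum((arr < lo) | (arr > hi)))
    if isinstance(values, pd.Series):
        return pd.Series(clipped, index=values.index, name=values.name), n_modified
    return clipped, n_modified
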