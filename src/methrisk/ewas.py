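"""Probe-wise epigenome-wide association with covariate adjustment.

Each probe's beta values are regressed (OLS, probe as the response) on the
predictor of interest — the substance-use factor score in the main
analysis, prenatal smoking in the biological-validation analysis — plus
covariates (sex and the five estimated cell-type proportions). Reported per
probe: the standardized coefficient ``std_beta = b * SD(x) / SD(y)`` (a
correlation-scale quantity), its SE, t statistic, two-sided p, and the
Benjamini-Hochberg q-value. Probes with ``std_beta < 0`` are labelled
hypomethylated (lower methylation with higher substance use) and
``std_beta > 0`` hypermethylated.

Also here: the 450k-style probe QC filter, the follow-forward re-test of
discovery DMPs at a later timepoint, per-probe cross-time autocorrelation,
and the within-time co-methylation (intercorrelation) structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylomeMatrix

__all__ = ["filter_probes", "bh_adjust", "run_ewas", "select_dmps", "DmpSet",
           "follow_forward", "probe_autocorrelation",
           "comethylation_structure", "compare_structures"]

QC_FLAGS = ("cross_reactive", "control_probe", "snp_at_sbe_maf_gt_5")

EWAS_COLUMNS = ["gene", "chrom", "pos", "std_beta", "se", "t", "p", "q",
                "n_used", "direction_label", "zero_variance"]


def filter_probes(annotation: pd.DataFrame) -> pd.Index:
    """QC filter: drop cross-reactive probes, sample-identification control
    probes, and probes with a common SNP (MAF > 5%) at the single-base
    extension. Returns the kept probe ids in their original order."""
    missing = [f for f in QC_FLAGS if f not in annotation.columns]
    if missing:
        raise ValueError(f"annotation lacks flag columns: {missing}")
    bad = annotation[list(QC_FLAGS)].any(axis=1)
    return annotation.index[~bad]


def bh_adjust(p_values: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the ascending order
    statistics, mapped back to input order. ``m_total`` supports adjusting a
    sub-vector against a larger family (``m_total >= len(p_values)``), as
    when the printed top hits of a genome-wide scan are re-adjusted against
    the full probe count.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    m = n if m_total is None else int(m_total)
    if m < n:
        raise ValueError("m_total must be at least len(p_values)")
    if n == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _align_inputs(M: MethylomeMatrix, outcome: pd.Series,
                  covariates: pd.DataFrame | None):
    frames = [outcome.rename("_outcome")]
    if covariates is not None and covariates.shape[1] > 0:
        frames.append(covariates)
    pheno = pd.concat(frames, axis=1).dropna()
    shared = M.sample_ids.intersection(pheno.index)
    if len(shared) == 0:
        raise ValueError("no shared complete-case samples")
    pheno = pheno.loc[shared]
    Y = M.beta.loc[shared].to_numpy(dtype=float)
    x = pheno["_outcome"].to_numpy(dtype=float)
    C = pheno.drop(columns="_outcome").to_numpy(dtype=float)
    return Y, x, C, shared


def run_ewas(M: MethylomeMatrix, outcome: pd.Series,
             covariates: pd.DataFrame | None = None,
             m_total: int | None = None) -> pd.DataFrame:
    """One OLS fit per probe: beta ~ predictor + covariates.

    Returns the per-probe association table (index = probe id) with
    BH q-values over all non-degenerate probes. ``m_total`` widens the BH
    family (used by the follow-forward stage's caller when adjusting a
    probe subset against a different family size).
    """
    Y, x, C, shared = _align_inputs(M, outcome, covariates)
    n = Y.shape[0]
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance")
    X = np.column_stack([np.ones(n), x, C])
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError("too few complete cases for the design")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coefs = XtX_inv @ (X.T @ Y)            # k x m
    resid = Y - X @ coefs
    dof = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    b = coefs[1]
    se = np.sqrt(sigma2 * XtX_inv[1, 1])

    sd_y = Y.std(axis=0, ddof=1)
    sd_x = x.std(ddof=1)
    zero_var = sd_y == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.nan)
        std_beta = np.where(zero_var, np.nan, b * sd_x / np.where(zero_var, 1, sd_y))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[zero_var] = np.nan

    q = np.full(Y.shape[1], np.nan)
    valid = ~zero_var
    if valid.any():
        q[valid] = bh_adjust(p[valid], m_total=m_total)

    ann = M.annotation.loc[M.probe_ids]
    table = pd.DataFrame({
        "gene": ann["gene"].to_numpy(),
        "chrom": ann["chrom"].to_numpy(),
        "pos": ann["pos"].to_numpy(),
        "std_beta": std_beta, "se": se, "t": t, "p": p, "q": q,
        "n_used": n,
        "direction_label": np.where(
            np.isnan(std_beta), "",
            np.where(std_beta < 0, "hypomethylated", "hypermethylated")),
        "zero_variance": zero_var,
    }, index=M.probe_ids.rename("probe_id"))
    return table


@dataclass
class DmpSet:
    """Discovery DMPs: probe ids ordered by significance with their
    standardized effects (the risk-score weights) and q-values."""

    table: pd.DataFrame                  # index probe_id: std_beta, p, q
    q_threshold: float = 0.05
    timepoint: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def weights(self) -> pd.Series:
        return self.table["std_beta"]

    def __len__(self) -> int:
        return len(self.table)


def select_dmps(ewas_table: pd.DataFrame, q_threshold: float = 0.05,
                timepoint: str = "") -> DmpSet:
    """Probes with q < threshold, sorted by p ascending (ties broken by
    probe id, lexicographic)."""
    hits = ewas_table[ewas_table["q"] < q_threshold].copy()
    # sort by p ascending, ties broken lexicographically on the probe id
    hits = (hits.assign(_pid=hits.index)
                .sort_values(["p", "_pid"], kind="stable")
                .drop(columns="_pid"))
    return DmpSet(table=hits[["std_beta", "p", "q"]], q_threshold=q_threshold,
                  timepoint=timepoint)


def follow_forward(dmps: DmpSet, M2: MethylomeMatrix, outcome: pd.Series,
                   covariates: pd.DataFrame | None = None,
                   q_threshold: float = 0.05) -> pd.DataFrame:
    """Re-test the discovery DMPs at a later timepoint.

    Same regression as :func:`run_ewas`, restricted to the DMP probes, with
    BH adjustment over the number of DMP tests only. Probes absent from the
    later-timepoint matrix are listed in ``table.attrs['missing_probes']``
    and excluded. The result table adds ``replicated`` (q < threshold) and
    ``nominal`` (unadjusted p < 0.05) columns.
    """
    present = [pid for pid in dmps.probe_ids if pid in M2.probe_ids]
    missing = [pid for pid in dmps.probe_ids if pid not in M2.probe_ids]
    if not present:
        raise ValueError("none of the DMPs are present at the later timepoint")
    table = run_ewas(M2.subset_probes(present), outcome, covariates)
    table["replicated"] = table["q"] < q_threshold
    table["nominal"] = table["p"] < 0.05
    table.attrs["missing_probes"] = missing
    return table


def probe_autocorrelation(M1: MethylomeMatrix, M2: MethylomeMatrix,
                          probe_ids: Sequence[str] | None = None
                          ) -> tuple[pd.DataFrame, dict]:
    """Per-probe Pearson correlation of beta values across timepoints.

    Returns the per-probe (r, p) table and a summary dict with the maximum,
    minimum and mean absolute correlation plus the count significant at
    p < 0.05 — the stability metrics used to judge whether discovery-stage
    methylation persists.
    """
    probes = pd.Index(probe_ids) if probe_ids is not None else M1.probe_ids
    shared = M1.sample_ids.intersection(M2.sample_ids)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    A = M1.beta.loc[shared, probes].to_numpy(dtype=float)
    B = M2.beta.loc[shared, probes].to_numpy(dtype=float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    denom = np.sqrt((A ** 2).sum(axis=0) * (B ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (A * B).sum(axis=0) / denom, np.nan)
    n = len(shared)
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    tstat = r_c * np.sqrt((n - 2) / (1 - r_c ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    table = pd.DataFrame({"r": r, "p": p}, index=probes.rename("probe_id"))
    ok = table.dropna()
    summary = {
        "r_max": float(ok["r"].max()),
        "r_min": float(ok["r"].min()),
        "mean_abs_r": float(ok["r"].abs().mean()),
        "n_significant": int((ok["p"] < 0.05).sum()),
        "n_probes": int(len(ok)),
        "n_samples": n,
    }
    return table, summary


def comethylation_structure(M: MethylomeMatrix, probe_ids: Sequence[str]
                            ) -> tuple[pd.DataFrame, dict]:
    """Pairwise Pearson correlation matrix across a probe set within one
    timepoint, with BH q-values over the probe pairs.

    Returns the correlation matrix and a summary dict (fraction of pairs
    with q < 0.05, extreme correlations, mean absolute off-diagonal r).
    """
    probes = list(probe_ids)
    if len(probes) < 2:
        raise ValueError("need at least 2 probes")
    X = M.beta.loc[:, probes].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant probe in co-methylation set")
    n = X.shape[0]
    C = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(len(probes), k=1)
    r = C[iu]
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    tstat = r_c * np.sqrt((n - 2) / (1 - r_c ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    q = bh_adjust(p)
    corr = pd.DataFrame(C, index=probes, columns=probes)
    summary = {
        "frac_significant": float((q < 0.05).mean()),
        "r_max": float(r.max()),
        "r_min": float(r.min()),
        "mean_abs_r": float(np.abs(r).mean()),
        "n_pairs": int(r.size),
    }
    return corr, summary


def compare_structures(C1: pd.DataFrame, C2: pd.DataFrame,
                       n_permutations: int = 999, seed: int = 0) -> dict:
    """Similarity of two co-methylation matrices over the same probes.

    Primary metric: Pearson correlation of the vectorized lower triangles.
    Secondary: a Mantel permutation p-value (probes relabelled jointly,
    seeded and reproducible).
    """
    if C1.shape != C2.shape:
        raise ValueError("correlation matrices differ in shape")
    A = C1.to_numpy(dtype=float)
    B = C2.loc[C1.index, C1.columns].to_numpy(dtype=float)
    k = A.shape[0]
    il = np.tril_indices(k, k=-1)
    obs = float(np.corrcoef(A[il], B[il])[0, 1])
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        Bp = B[np.ix_(perm, perm)]
        if np.corrcoef(A[il], Bp[il])[0, 1] >= obs:
            count += 1
    return {"similarity": obs,
            "mantel_p": count / (n_permutations + 1),
            "n_permutations": n_permutations}
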