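"""Reference-based cell-composition estimation.

Houseman-style constrained projection: for each sample, the beta values at
the reference probes are projected onto the signature matrix by solving

    minimize  || beta - R pi ||^2    subject to  pi >= 0  (and a sum rule)

per sample. The default sum rule is ``sum <= 1`` — the constrained
projection of the cited method does not force the estimates onto the
simplex — with ``sum == 1`` available as a config switch. The resulting
proportions (CD8 T, CD4 T, NK, B cells, monocytes in the blood reference
used here) enter every probe-wise association model as covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import MethylomeMatrix, ReferencePanel

__all__ = ["estimate_proportions"]

_CONSTRAINTS = ("sum_le_1", "sum_eq_1", "none")


def _simplex_solve(R: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact minimizer of ||R pi - y||^2 with pi >= 0 and sum(pi) = 1.

    The optimum's support solves the equality-constrained normal equations
    with the zero coordinates dropped, so enumerating supports (K is the
    number of cell types, small) and keeping the best feasible stationary
    point is exact.
    """
    k = R.shape[1]
    best, best_obj = None, np.inf
    for mask in range(1, 1 << k):
        idx = [j for j in range(k) if mask >> j & 1]
        Rs = R[:, idx]
        ks = len(idx)
        kkt = np.zeros((ks + 1, ks + 1))
        kkt[:ks, :ks] = Rs.T @ Rs
        kkt[:ks, ks] = 1.0
        kkt[ks, :ks] = 1.0
        rhs = np.concatenate([Rs.T @ y, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            continue
        pi_s = sol[:ks]
        if (pi_s < -1e-12).any():
            continue
        resid = Rs @ pi_s - y
        obj = float(resid @ resid)
        if obj < best_obj - 1e-15:
            best_obj = obj
            best = np.zeros(k)
            best[idx] = np.clip(pi_s, 0.0, None)
    if best is None:  # cannot happen for full-rank R, defensive only
        raise RuntimeError("simplex projection failed")
    return best / best.sum()


def _project_sample(R: np.ndarray, y: np.ndarray, constraint: str) -> np.ndarray:
    """Solve the per-sample non-negative least-squares projection exactly."""
    if constraint == "sum_eq_1":
        return _simplex_solve(R, y)
    pi, _ = optimize.nnls(R, y)
    if constraint == "none" or pi.sum() <= 1.0:
        return pi
    # the sum <= 1 constraint binds: the optimum lies on the simplex face
    return _simplex_solve(R, y)


def estimate_proportions(M: MethylomeMatrix, panel: ReferencePanel,
                         constraint: str = "sum_le_1") -> pd.DataFrame:
    """Estimate cell-type proportions for every sample in ``M``.

    Returns a DataFrame (samples x cell types, panel column order) of
    non-negative proportions obeying the chosen sum constraint. The
    estimation is deterministic.
    """
    if constraint not in _CONSTRAINTS:
        raise ValueError(f"constraint must be one of {_CONSTRAINTS}")
    probes = panel.probe_ids
    missing = probes.difference(M.probe_ids)
    if len(missing):
        raise ValueError(f"panel probes absent from matrix: {list(missing[:5])}")
    R = panel.signatures.to_numpy(dtype=float)
    if R.shape[0] <= R.shape[1]:
        raise ValueError("need more reference probes than cell types")
    rank = np.linalg.matrix_rank(R)
    if rank < R.shape[1]:
        corr = np.corrcoef(R, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            "rank-deficient reference panel; most collinear cell types: "
            f"{panel.cell_types[i]} vs {panel.cell_types[j]}")

    B = M.beta.loc[:, probes].to_numpy(dtype=float)
    out = np.empty((B.shape[0], R.shape[1]))
    for i in range(B.shape[0]):
        out[i] = _project_sample(R, B[i], constraint)
    return pd.DataFrame(out, index=M.sample_ids, columns=panel.cell_types)
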