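"""Cumulative weighted DNA-methylation risk score and its correlates.

Following the polygenic-risk-score recipe, each sample's score is the sum
of its raw beta values at the discovery DMPs, each multiplied by the
discovery-stage standardized regression coefficient:

    score_i = sum_j  w_j * beta_ij ,   w_j = discovery std_beta of probe j.

The weights preserve each DMP's relative predictive importance (unlike a
plain mean across DMPs). A sensitivity variant drops DMPs with known mQTLs
to limit genetic confounding. Downstream utilities: the prenatal-exposure
correlation screen (Pearson r with BH adjustment over the exposure family)
and age-of-onset correlations within the endorsing subgroups.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylomeMatrix, RiskScore
from .ewas import DmpSet, bh_adjust

__all__ = ["compute_mrs", "exclude_mqtl_probes", "screen_exposures",
           "onset_correlation"]


def compute_mrs(M: MethylomeMatrix, dmps: DmpSet,
                variant: str = "full") -> RiskScore:
    """Exact weighted sum of raw beta values over the DMP probes."""
    probes = dmps.probe_ids
    missing = [p for p in probes if p not in M.probe_ids]
    if missing:
        raise KeyError(f"DMP probes absent from matrix: {missing}")
    w = dmps.weights
    scores = M.beta.loc[:, probes].to_numpy(dtype=float) @ w.to_numpy(dtype=float)
    return RiskScore(
        scores=pd.Series(scores, index=M.sample_ids, name=f"mrs_{variant}"),
        weights=w.copy(),
        variant=variant,
        metadata={"timepoint": dmps.timepoint,
                  "q_threshold": dmps.q_threshold,
                  "n_probes": len(probes)},
    )


def exclude_mqtl_probes(dmps: DmpSet, mqtl_table: pd.DataFrame
                        ) -> tuple[DmpSet, dict]:
    """Drop DMPs present in the mQTL lookup table.

    Returns the reduced set plus a report with the removed count and its
    cis/trans split.
    """
    if len(mqtl_table) and "probe_id" not in mqtl_table.columns:
        raise ValueError("mqtl_table needs a probe_id column")
    listed = set(mqtl_table["probe_id"]) if len(mqtl_table) else set()
    removed = [p for p in dmps.probe_ids if p in listed]
    kept = dmps.table.drop(index=removed)
    types = (mqtl_table.set_index("probe_id").loc[removed, "type"]
             if removed else pd.Series(dtype=object))
    report = {
        "n_removed": len(removed),
        "removed_probe_ids": removed,
        "n_cis": int((types == "cis").sum()),
        "n_trans": int((types == "trans").sum()),
    }
    reduced = DmpSet(table=kept, q_threshold=dmps.q_threshold,
                     timepoint=dmps.timepoint,
                     metadata={**dmps.metadata, "variant": "mqtl_excluded"})
    return reduced, report


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError("fewer than 3 complete cases")
    xs, ys = x[mask], y[mask]
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("constant column in correlation")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def screen_exposures(score: RiskScore, outcome: pd.Series,
                     exposures: pd.DataFrame) -> pd.DataFrame:
    """Pearson screen of the risk score (and the substance-use outcome)
    against each prenatal exposure.

    Returns a long table with one row per (variable, exposure) pair holding
    r, p and the BH q computed over the exposure family within each row
    variable — the layout of the published exposure-screen table.
    """
    targets = {"dnam_risk": score.scores, "substance_use": outcome}
    rows = []
    for var_name, series in targets.items():
        aligned = pd.concat([series.rename("_v"), exposures], axis=1)
        ps = []
        for exp_name in exposures.columns:
            r, p, n = _pearson(aligned["_v"].to_numpy(dtype=float),
                               aligned[exp_name].to_numpy(dtype=float))
            rows.append({"variable": var_name, "exposure": exp_name,
                         "r": r, "p": p, "n": n})
            ps.append(p)
        qs = bh_adjust(np.array(ps))
        for off, q in enumerate(qs):
            rows[len(rows) - len(qs) + off]["q"] = float(q)
    return pd.DataFrame(rows)


def onset_correlation(score: RiskScore, cohort: pd.DataFrame,
                      substances: Sequence[str] = ("cigarette", "cannabis",
                                                   "alcohol")) -> pd.DataFrame:
    """Correlation of the risk score with age of first use, within users.

    Onset ages exist only for endorsers (``endorsed_<substance>`` == 1);
    returns (r, p, n) per substance. A negative r means higher cumulative
    methylation risk goes with earlier onset.
    """
    rows = []
    for sub in substances:
        endorse_col = f"endorsed_{sub}"
        age_col = f"onset_age_{sub}"
        if endorse_col not in cohort.columns or age_col not in cohort.columns:
            raise KeyError(f"cohort lacks {endorse_col}/{age_col}")
        mask = cohort[endorse_col] == 1
        sub_ids = cohort.index[mask]
        x = score.scores.reindex(sub_ids).to_numpy(dtype=float)
        y = cohort.loc[sub_ids, age_col].to_numpy(dtype=float)
        r, p, n = _pearson(x, y)
        rows.append({"substance": sub, "r": r, "p": p, "n_endorse": n})
    return pd.DataFrame(rows)
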