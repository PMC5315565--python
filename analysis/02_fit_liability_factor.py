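#!/usr/bin/env python
"""Fit the substance-use liability factor model and extract its scores.

Confirmatory factor analysis of the eight adolescent substance-use
indicators: three first-order factors (tobacco, cannabis, alcohol — each
pooling repeated assessments at ages 14-18) under a single second-order
liability factor. The standardized second-order factor score is the
outcome of every downstream epigenome-wide analysis.
"""

import json
from pathlib import Path

from methrisk.cfa import fit_cfa
from methrisk.io import read_fixture

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    fx = read_fixture(ROOT / "scratch" / "cohort")
    fit = fit_cfa(fx["cohort"])
    fit.factor_score_table.to_csv(ROOT / "scratch" / "factor_scores.csv")
    with open(ROOT / "results" / "02_cfa_fit.json", "w") as fh:
        json.dump(fit.summary(), fh, indent=1)
    print(f"chi2({fit.df}) = {fit.chi_square:.2f}, p = {fit.p_chi:.3g}; "
          f"CFI = {fit.cfi:.3f}, TLI = {fit.tli:.3f}, "
          f"RMSEA = {fit.rmsea:.3f} "
          f"[{fit.rmsea_ci90[0]:.3f}, {fit.rmsea_ci90[1]:.3f}]")
    lo = fit.loadings_std["loading"]
    print(f"standardized loadings {lo.min():.2f}-{lo.max():.2f}; "
          f"admissible = {fit.admissible}")
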