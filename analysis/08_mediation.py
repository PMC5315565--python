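#!/usr/bin/env python
"""Step 3b: path-analytic mediation of screened exposures through the
methylation risk score.

Exposures that survived the screen enter a recursive path model
(exposure -> DNAm risk score -> substance-use factor) with 10,000-draw
case-resampling bootstrap CIs for every path and indirect effect; the model
is re-run per substance (first-order factor scores) and, where an outcome
carries an outlier beyond 3 SD, with winsorized data.
"""

import json
from pathlib import Path

import pandas as pd

from methrisk.io import read_fixture
from methrisk.mediation import (bootstrap_ci, fit_path_model,
                                per_substance_mediation, winsorize)

ROOT = Path(__file__).resolve().parents[1]
SEED = 2016

if __name__ == "__main__":
    fx = read_fixture(ROOT / "scratch" / "cohort")
    scores = pd.read_csv(ROOT / "scratch" / "factor_scores.csv", index_col=0)
    risk = pd.read_csv(ROOT / "scratch" / "risk_scores.csv", index_col=0)
    screen = pd.read_csv(ROOT / "results" / "07_exposure_screen.csv")
    hits = screen[(screen["variable"] == "dnam_risk")
                  & (screen["q"] < 0.05)]["exposure"].tolist()
    if not hits:
        raise SystemExit("no exposure passed the screen; nothing to mediate")

    exposures = fx["cohort"][hits]
    mediator = risk["score_full"]
    outcome = scores["substance_use"]

    fit = fit_path_model(exposures, mediator, outcome)
    fit = bootstrap_ci(exposures, mediator, outcome, B=10_000, seed=SEED,
                       fit=fit)
    per_sub = per_substance_mediation(
        exposures, mediator, scores[["tobacco", "cannabis", "alcohol"]],
        B=2000, seed=SEED)

    winsor_reruns = {}
    for sub in ("tobacco", "cannabis", "alcohol"):
        col = scores[sub]
        wins, n_mod = winsorize(col, k=3)
        if n_mod:
            refit = fit_path_model(exposures, mediator, wins)
            winsor_reruns[sub] = {"n_winsorized": n_mod,
                                  "indirect": refit.indirect.to_dict()}

    out = {
        "screened_exposures": hits,
        "model": fit.summary(),
        "per_substance": {k: v.summary() for k, v in per_sub.items()},
        "winsorized_reruns": winsor_reruns,
    }
    with open(ROOT / "results" / "08_mediation.json", "w") as fh:
        json.dump(out, fh, indent=1, default=str)
    for name in hits:
        ci = fit.bootstrap["indirect"][name]
        print(f"indirect effect of {name}: b = {fit.indirect[name]:.3f}, "
              f"bootstrapped 95% CI = {ci['lo']:.3f}-{ci['hi']:.3f}")
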