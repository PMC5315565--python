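#!/usr/bin/env python
"""Step 3a: cumulative methylation risk score, mQTL sensitivity, and the
prenatal-exposure screen.

Builds the weighted DNAm risk score (DMP betas x discovery standardized
coefficients), its mQTL-excluded variant, screens both the score and the
substance-use outcome against the six prenatal exposures with BH-corrected
Pearson correlations, and correlates the score with age of first use among
endorsers.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from methrisk.ewas import DmpSet
from methrisk.io import read_fixture
from methrisk.mrs import (compute_mrs, exclude_mqtl_probes,
                          onset_correlation, screen_exposures)
from methrisk.simulate import EXPOSURE_COLUMNS

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    fx = read_fixture(ROOT / "scratch" / "cohort")
    dmps = DmpSet(table=pd.read_csv(ROOT / "scratch" / "dmps.tsv", sep="\t",
                                    index_col=0), timepoint="birth")
    scores = pd.read_csv(ROOT / "scratch" / "factor_scores.csv", index_col=0)

    full = compute_mrs(fx["meth1"], dmps)
    reduced_set, mqtl_report = exclude_mqtl_probes(dmps, fx["mqtl_table"])
    reduced = compute_mrs(fx["meth1"], reduced_set, variant="mqtl_excluded")
    pd.DataFrame({"score_full": full.scores,
                  "score_mqtl_excluded": reduced.scores}
                 ).to_csv(ROOT / "scratch" / "risk_scores.csv")

    screen = screen_exposures(full, scores["substance_use"],
                              fx["cohort"][list(EXPOSURE_COLUMNS)])
    screen.to_csv(ROOT / "results" / "07_exposure_screen.csv", index=False)
    onset = onset_correlation(full, fx["cohort"])

    summary = {
        "n_dmps_in_score": len(dmps),
        "mqtl_excluded": {k: v for k, v in mqtl_report.items()
                          if k != "removed_probe_ids"},
        "full_vs_reduced_r": round(float(
            np.corrcoef(full.scores, reduced.scores)[0, 1]), 4),
        "screen_significant": screen[(screen["variable"] == "dnam_risk")
                                     & (screen["q"] < 0.05)]["exposure"].tolist(),
        "onset": onset.round(4).to_dict(orient="records"),
    }
    with open(ROOT / "results" / "07_risk_score.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))
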