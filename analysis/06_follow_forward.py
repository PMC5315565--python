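#!/usr/bin/env python
"""Step 2: temporal stability of the discovery DMPs.

Re-tests the birth DMPs against the same liability outcome using age-7
methylation (follow-forward, BH over the DMP set only), then quantifies
per-probe birth-to-age-7 autocorrelation and compares the within-time
co-methylation (intercorrelation) structure between timepoints.
"""

import json
from pathlib import Path

import pandas as pd

from methrisk.ewas import (DmpSet, comethylation_structure,
                           compare_structures, follow_forward,
                           probe_autocorrelation)
from methrisk.io import read_fixture

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    fx = read_fixture(ROOT / "scratch" / "cohort")
    dmp_table = pd.read_csv(ROOT / "scratch" / "dmps.tsv", sep="\t",
                            index_col=0)
    dmps = DmpSet(table=dmp_table, timepoint="birth")
    scores = pd.read_csv(ROOT / "scratch" / "factor_scores.csv", index_col=0)
    cells2 = pd.read_csv(ROOT / "scratch" / "cell_proportions_age7.csv",
                         index_col=0)
    cov2 = pd.concat([fx["cohort"][["sex"]], cells2], axis=1)

    ff = follow_forward(dmps, fx["meth2"], scores["substance_use"], cov2)
    ff.to_csv(ROOT / "scratch" / "follow_forward.tsv", sep="\t")
    _, auto = probe_autocorrelation(fx["meth1"], fx["meth2"], dmps.probe_ids)
    c1, s1 = comethylation_structure(fx["meth1"], dmps.probe_ids)
    c2, s2 = comethylation_structure(fx["meth2"], dmps.probe_ids)
    comp = compare_structures(c1, c2, seed=2016)

    summary = {
        "n_dmps": len(dmps),
        "n_replicated_q_lt_05": int(ff["replicated"].sum()),
        "n_nominal_p_lt_05": int(ff["nominal"].sum()),
        "autocorrelation": {k: round(v, 4) if isinstance(v, float) else v
                            for k, v in auto.items()},
        "comethylation_birth": {k: round(v, 4) for k, v in s1.items()},
        "comethylation_age7": {k: round(v, 4) for k, v in s2.items()},
        "structure_similarity": {k: round(v, 4) if isinstance(v, float) else v
                                 for k, v in comp.items()},
    }
    with open(ROOT / "results" / "06_follow_forward.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))
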