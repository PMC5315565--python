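#!/usr/bin/env python
"""Step 1: genome-wide association of neonatal methylation with the
substance-use liability score.

One OLS model per probe (methylation as response), adjusted for sex and the
five estimated cell proportions, with Benjamini-Hochberg correction.
Probes at q < 0.05 form the DMP set carried through the rest of the
analysis; the DMP table (published-table column layout) goes to results/.
"""

import json
from pathlib import Path

import pandas as pd

from methrisk.ewas import filter_probes, run_ewas, select_dmps
from methrisk.io import read_fixture
from methrisk.pipeline import _export_ewas

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    fx = read_fixture(ROOT / "scratch" / "cohort")
    m1 = fx["meth1"].subset_probes(filter_probes(fx["meth1"].annotation))
    scores = pd.read_csv(ROOT / "scratch" / "factor_scores.csv", index_col=0)
    cells = pd.read_csv(ROOT / "scratch" / "cell_proportions_birth.csv",
                        index_col=0)
    cov = pd.concat([fx["cohort"][["sex"]], cells], axis=1)
    table = run_ewas(m1, scores["substance_use"], cov)
    table.to_csv(ROOT / "scratch" / "ewas_birth_full.tsv", sep="\t")

    dmps = select_dmps(table, q_threshold=0.05, timepoint="birth")
    dmps.table.to_csv(ROOT / "scratch" / "dmps.tsv", sep="\t")
    _export_ewas(table.loc[dmps.probe_ids], ROOT / "results" / "04_dmp_table.tsv")

    truth_dmps = set(fx["truth"]["dmp_ids"])
    n_hypo = int((dmps.table["std_beta"] < 0).sum())
    summary = {
        "n_probes_tested": int((~table["zero_variance"]).sum()),
        "n_dmps_q_lt_05": len(dmps),
        "n_hypomethylated": n_hypo,
        "n_hypermethylated": len(dmps) - n_hypo,
        "n_planted_recovered": len(set(dmps.probe_ids) & truth_dmps),
        "n_planted": len(truth_dmps),
        "top_probe": dmps.probe_ids[0] if len(dmps) else None,
        "top_p": float(dmps.table["p"].iloc[0]) if len(dmps) else None,
        "top_q": float(dmps.table["q"].iloc[0]) if len(dmps) else None,
    }
    with open(ROOT / "results" / "04_ewas_birth.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))
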