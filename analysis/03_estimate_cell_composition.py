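#!/usr/bin/env python
"""Estimate leukocyte composition at both timepoints.

Reference-based constrained projection of each sample's beta values at the
panel probes onto the five-cell-type signature matrix (CD8 T, CD4 T, NK,
B cells, monocytes). The estimated proportions are the cell-composition
covariates of every probe-wise association model.
"""

import json
from pathlib import Path

import numpy as np

from methrisk.cellmix import estimate_proportions
from methrisk.io import read_fixture

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    fx = read_fixture(ROOT / "scratch" / "cohort")
    props = {}
    for key, label in (("meth1", "birth"), ("meth2", "age7")):
        p = estimate_proportions(fx[key], fx["panel"])
        p.to_csv(ROOT / "scratch" / f"cell_proportions_{label}.csv")
        props[label] = p
    truth = fx["truth"]
    import pandas as pd
    true1 = pd.DataFrame(truth["cell_proportions_t1"]).T
    recov = {ct: float(np.corrcoef(props["birth"][ct],
                                   true1.loc[props["birth"].index, ct])[0, 1])
             for ct in props["birth"].columns}
    summary = {
        "mean_proportions_birth": props["birth"].mean().round(4).to_dict(),
        "mean_proportions_age7": props["age7"].mean().round(4).to_dict(),
        "recovery_r_vs_true_mixtures": {k: round(v, 3) for k, v in recov.items()},
    }
    with open(ROOT / "results" / "03_cell_composition.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))
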