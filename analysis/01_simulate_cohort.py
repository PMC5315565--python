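#!/usr/bin/env python
"""Simulate the desk-scale study cohort and persist it for the later stages.

Generates a two-timepoint methylation cohort (500 children, 20,000 probes;
cord blood at birth, whole blood at age 7) with 65 probes loading on the
latent substance-use liability, 5 of them under mQTL control, 30 probes
responding directly to prenatal maternal smoking, Dirichlet cell mixtures
over five leukocyte types, and a no-persistence second timepoint. The full
fixture (beta matrices are large) goes to scratch/; a small design summary
goes to results/.
"""

import json
from pathlib import Path

from methrisk.io import write_fixture
from methrisk.simulate import SimConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
STUDY_SEED = 2016

if __name__ == "__main__":
    cfg = SimConfig(n_samples=500, n_probes=20_000, seed=STUDY_SEED)
    out = simulate_cohort(cfg)
    m1, m2, cohort, truth, panel, mqtl = out
    fixture_dir = ROOT / "scratch" / "cohort"
    write_fixture(fixture_dir, *out, config=cfg)

    summary = {
        "seed": STUDY_SEED,
        "n_samples": m1.n_samples,
        "n_probes": m1.n_probes,
        "n_planted_dmps": len(truth.dmp_ids),
        "n_mqtl_dmps": len(truth.mqtl_probe_ids),
        "pct_female": round(100 * cohort["sex"].mean(), 1),
        "pct_smoking_exposed": round(100 * cohort["maternal_smoking"].mean(), 1),
        "cell_types": list(panel.cell_types),
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    with open(results / "01_cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"wrote fixture to {fixture_dir}")
    print(json.dumps(summary, indent=1))
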