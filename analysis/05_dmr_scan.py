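#!/usr/bin/env python
"""Step 1 (regional): spatially-correlated p-value scan for wider
differentially methylated regions.

Comb-p style: distance-binned autocorrelation of probit-transformed EWAS
p-values, Stouffer-Liptak-Kechris smoothing in 500-bp windows, region
calling at the 1e-4 seed threshold, and Sidak correction of each region's
combined p for the genome footprint covered by the track.
"""

import json
from pathlib import Path

import pandas as pd

from methrisk.dmr import call_dmrs, make_track

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    table = pd.read_csv(ROOT / "scratch" / "ewas_birth_full.tsv", sep="\t",
                        index_col=0, dtype={"chrom": str})
    track = make_track(table)
    calls = call_dmrs(track, p_threshold=1e-4, window=500)
    calls.to_csv(ROOT / "results" / "05_dmr_calls.tsv", sep="\t", index=False)
    multi = calls[(calls["n_probes"] >= 2) & (calls["p_sidak"] < 0.05)] \
        if len(calls) else calls
    summary = {
        "n_candidate_regions": int(len(calls)),
        "n_sidak_significant": int((calls["p_sidak"] < 0.05).sum())
        if len(calls) else 0,
        "n_sidak_significant_multiprobe": int(len(multi)),
    }
    with open(ROOT / "results" / "05_dmr_scan.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))
    if len(multi) == 0:
        print("no multi-probe region survives genome-wide correction — the "
              "planted association signal is spatially isolated")
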