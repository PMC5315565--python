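"""Shared fixtures: small planted cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from methrisk.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300 samples x 800 probes, 10 planted DMPs (2 under mQTL control)."""
    cfg = SimConfig(n_samples=300, n_probes=800, n_dmps=10, n_mqtl_dmps=2,
                    n_panel_probes=60, n_sex_probes=20,
                    exposure_effects={"maternal_smoking": (8, 0.35)},
                    seed=42)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """Larger cohort for recovery checks: 600 x 3000, 65 planted DMPs."""
    cfg = SimConfig(n_samples=600, n_probes=3000, seed=7)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def toy_annotation():
    probes = [f"cg{i:08d}" for i in range(1, 11)]
    ann = pd.DataFrame({
        "chrom": ["1"] * 10,
        "pos": np.arange(100, 1100, 100),
        "gene": [""] * 10,
        "cross_reactive": [False] * 10,
        "control_probe": [False] * 10,
        "snp_at_sbe_maf_gt_5": [False] * 10,
    }, index=pd.Index(probes, name="probe_id"))
    ann.loc[probes[1], "cross_reactive"] = True
    ann.loc[probes[4], "control_probe"] = True
    ann.loc[probes[7], "snp_at_sbe_maf_gt_5"] = True
    return ann
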