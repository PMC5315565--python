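"""Plain-text fixture I/O.

Everything is written as TSV/CSV/JSON so a cohort written with a fixed seed
has stable checksums and round-trips exactly: beta matrices as TSV with
samples in rows (first column the sample id, header the probe ids), the
probe annotation as a BED-like TSV, the cohort table as CSV, and ground
truth / config as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .containers import GroundTruth, MethylomeMatrix, ReferencePanel
from .simulate import SimConfig

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly

FIXTURE_FILES = {
    "beta_t1": "beta_birth.tsv",
    "beta_t2": "beta_age7.tsv",
    "annotation": "annotation.bed.tsv",
    "cohort": "cohort.csv",
    "panel": "reference_panel.tsv",
    "mqtl": "mqtl_table.tsv",
    "truth": "ground_truth.json",
    "config": "sim_config.json",
}


def write_fixture(outdir: str | Path,
                  meth1: MethylomeMatrix, meth2: MethylomeMatrix,
                  cohort: pd.DataFrame, truth: GroundTruth,
                  panel: ReferencePanel, mqtl_table: pd.DataFrame,
                  config: SimConfig | None = None) -> dict[str, Path]:
    """Persist a simulated cohort; returns the mapping of written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in FIXTURE_FILES.items()}

    meth1.beta.to_csv(paths["beta_t1"], sep="\t", float_format=_FLOAT_FMT)
    meth2.beta.to_csv(paths["beta_t2"], sep="\t", float_format=_FLOAT_FMT)

    ann = meth1.annotation.reset_index()
    ann = ann[["chrom", "pos", "probe_id", "gene",
               "cross_reactive", "control_probe", "snp_at_sbe_maf_gt_5"]]
    ann.to_csv(paths["annotation"], sep="\t", index=False)

    cohort.to_csv(paths["cohort"], float_format=_FLOAT_FMT)
    panel.signatures.to_csv(paths["panel"], sep="\t", float_format=_FLOAT_FMT)
    mqtl_table.to_csv(paths["mqtl"], sep="\t", index=False)

    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
    if config is not None:
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)
    else:
        paths.pop("config")
    return paths


def _read_annotation(path: Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ann["gene"] = ann["gene"].fillna("")
    for flag in ("cross_reactive", "control_probe", "snp_at_sbe_maf_gt_5"):
        ann[flag] = ann[flag].astype(bool)
    return ann.set_index("probe_id")


def read_fixture(outdir: str | Path) -> dict[str, Any]:
    """Load a fixture written by :func:`write_fixture`.

    Returns a dict with keys ``meth1``, ``meth2``, ``cohort``, ``panel``,
    ``mqtl_table``, ``truth`` (raw JSON dict) and, when present, ``config``
    (a :class:`SimConfig`).
    """
    outdir = Path(outdir)
    ann = _read_annotation(outdir / FIXTURE_FILES["annotation"])
    beta1 = pd.read_csv(outdir / FIXTURE_FILES["beta_t1"], sep="\t", index_col=0)
    beta2 = pd.read_csv(outdir / FIXTURE_FILES["beta_t2"], sep="\t", index_col=0)
    out: dict[str, Any] = {
        "meth1": MethylomeMatrix(beta=beta1, annotation=ann, timepoint="birth"),
        "meth2": MethylomeMatrix(beta=beta2, annotation=ann, timepoint="age7"),
        "cohort": pd.read_csv(outdir / FIXTURE_FILES["cohort"], index_col=0),
        "panel": ReferencePanel(signatures=pd.read_csv(
            outdir / FIXTURE_FILES["panel"], sep="\t", index_col=0)),
        "mqtl_table": pd.read_csv(outdir / FIXTURE_FILES["mqtl"], sep="\t"),
    }
    with open(outdir / FIXTURE_FILES["truth"]) as fh:
        out["truth"] = json.load(fh)
    cfg_path = outdir / FIXTURE_FILES["config"]
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = json.load(fh)
        for key in ("factor_loadings", "cell_types", "dirichlet_alpha"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in raw[key]) if key == "factor_loadings" \
                    else tuple(raw[key])
        raw["exposure_effects"] = {k: tuple(v) for k, v
                                   in raw.get("exposure_effects", {}).items()}
        out["config"] = SimConfig(**raw)
    return out
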