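"""End-to-end orchestration of the prospective methylation analysis.

Stage order mirrors the study's analysis plan: simulate (or load) the
cohort -> fit the substance-use CFA and extract factor scores -> estimate
cell composition -> probe-wise EWAS at birth with sex + cell covariates ->
spatially-correlated DMR scan -> follow-forward re-test at age 7 plus
autocorrelation and co-methylation structure -> cumulative weighted
methylation risk score (full and mQTL-excluded) -> prenatal-exposure
screen -> path-analytic mediation restricted to the screened exposures,
with bootstrap CIs. The mediation stage is skipped, with the reason
recorded, when no DMPs or no screened exposures survive their q < 0.05
gates. A fixed config (including the seed) reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellmix import estimate_proportions
from .cfa import FactorModelSpec, fit_cfa
from .dmr import call_dmrs, make_track
from .ewas import (comethylation_structure, compare_structures, filter_probes,
                   follow_forward, probe_autocorrelation, run_ewas,
                   select_dmps)
from .io import read_fixture
from .mediation import bootstrap_ci, fit_path_model, per_substance_mediation
from .mrs import (compute_mrs, exclude_mqtl_probes, onset_correlation,
                  screen_exposures)
from .simulate import EXPOSURE_COLUMNS, SimConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

TABLE_EXPORT_COLUMNS = {
    "probe_id": "Probe", "gene": "Gene", "chrom": "Chr",
    "feature": "Genomic location", "pos": "Position",
    "std_beta": "Std B", "p": "P-value", "q": "q-value",
}


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one pipeline run.

    Exactly one of ``sim`` (a :class:`SimConfig` for a synthetic cohort) or
    ``fixture_dir`` (a directory written by :func:`methrisk.io.write_fixture`)
    must be provided.
    """

    sim: SimConfig | None = None
    fixture_dir: str | None = None
    outdir: str = "pipeline_out"
    q_dmp: float = 0.05
    dmr_seed_p: float = 1e-4
    dmr_window: int = 500
    bootstrap_B: int = 10_000
    seed: int = 0
    screen_q: float = 0.05
    cell_constraint: str = "sum_le_1"

    def validate(self) -> None:
        if (self.sim is None) == (self.fixture_dir is None):
            raise ValueError("provide exactly one of sim / fixture_dir")
        for name in ("q_dmp", "dmr_seed_p", "screen_q"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            if "exposure_effects" in sim_raw:
                sim_raw["exposure_effects"] = {
                    k: tuple(v) for k, v in sim_raw["exposure_effects"].items()}
            cfg.sim = SimConfig(**sim_raw)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _export_ewas(table: pd.DataFrame, path: Path, top: int | None = None) -> None:
    out = table.reset_index().rename(columns={"index": "probe_id"})
    if "feature" not in out.columns:
        out["feature"] = ""
    out = out.sort_values("p", kind="stable")
    if top is not None:
        out = out.head(top)
    out = out[list(TABLE_EXPORT_COLUMNS)].rename(columns=TABLE_EXPORT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report dict (also written to
    ``<outdir>/report.json`` with per-stage artifact files alongside)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.echo(), default=str)),
        "stages": {},
    }

    # ---- stage: data ----------------------------------------------------
    if config.sim is not None:
        meth1, meth2, cohort, truth, panel, mqtl_table = simulate_cohort(config.sim)
    else:
        fx = read_fixture(config.fixture_dir)
        meth1, meth2 = fx["meth1"], fx["meth2"]
        cohort, panel, mqtl_table = fx["cohort"], fx["panel"], fx["mqtl_table"]
        truth = None
    report["stages"]["data"] = {
        "n_samples": meth1.n_samples, "n_probes": meth1.n_probes,
        "source": "simulated" if config.sim is not None else "fixture",
    }

    # ---- stage: probe QC filter -----------------------------------------
    kept = filter_probes(meth1.annotation)
    n_removed = meth1.n_probes - len(kept)
    if n_removed:
        meth1 = meth1.subset_probes(kept)
        meth2 = meth2.subset_probes([p for p in kept if p in meth2.probe_ids])
    report["stages"]["probe_filter"] = {
        "n_kept": int(len(kept)), "n_removed": int(n_removed)}

    # ---- stage: substance-use CFA ---------------------------------------
    spec = FactorModelSpec()
    cfa_fit = fit_cfa(cohort, spec)
    scores = cfa_fit.factor_score_table
    outcome = scores[spec.second_order]
    first_order = scores[spec.factor_names]
    report["stages"]["cfa"] = cfa_fit.summary()
    scores.to_csv(outdir / "factor_scores.csv")

    # ---- stage: cell composition ----------------------------------------
    cells1 = estimate_proportions(meth1, panel, constraint=config.cell_constraint)
    cells2 = estimate_proportions(meth2, panel, constraint=config.cell_constraint)
    cells1.to_csv(outdir / "cell_proportions_birth.csv")
    report["stages"]["cell_mix"] = {
        "cell_types": list(cells1.columns),
        "mean_proportions_birth": cells1.mean().round(4).to_dict(),
    }

    # ---- stage: EWAS at birth -------------------------------------------
    cov1 = pd.concat([cohort[["sex"]], cells1], axis=1)
    ewas_birth = run_ewas(meth1, outcome, cov1)
    _export_ewas(ewas_birth, outdir / "ewas_birth_top.tsv", top=100)
    dmps = select_dmps(ewas_birth, q_threshold=config.q_dmp, timepoint="birth")
    n_hypo = int((dmps.table["std_beta"] < 0).sum())
    report["stages"]["ewas_birth"] = {
        "n_tested": int((~ewas_birth["zero_variance"]).sum()),
        "n_dmps": len(dmps), "n_hypomethylated": n_hypo,
        "n_hypermethylated": len(dmps) - n_hypo,
    }
    dmps.table.to_csv(outdir / "dmps.tsv", sep="\t")

    # ---- stage: DMR scan -------------------------------------------------
    track = make_track(ewas_birth)
    dmrs = call_dmrs(track, p_threshold=config.dmr_seed_p,
                     window=config.dmr_window)
    sig_dmrs = dmrs[dmrs["p_sidak"] < 0.05] if len(dmrs) else dmrs
    dmrs.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
    report["stages"]["dmr"] = {
        "n_candidate_regions": int(len(dmrs)),
        "n_significant_sidak": int(len(sig_dmrs)),
    }

    # ---- stage: follow-forward + temporal structure ----------------------
    if len(dmps) == 0:
        report["stages"]["follow_forward"] = {"skipped": "no DMPs at birth"}
        report["stages"]["temporal"] = {"skipped": "no DMPs at birth"}
    else:
        cov2 = pd.concat([cohort[["sex"]], cells2], axis=1)
        ff = follow_forward(dmps, meth2, outcome, cov2, q_threshold=config.q_dmp)
        ff.to_csv(outdir / "follow_forward.tsv", sep="\t")
        report["stages"]["follow_forward"] = {
            "n_replicated": int(ff["replicated"].sum()),
            "n_nominal": int(ff["nominal"].sum()),
            "missing_probes": ff.attrs["missing_probes"],
        }
        _, auto_summary = probe_autocorrelation(meth1, meth2, dmps.probe_ids)
        temporal = {"autocorrelation": auto_summary}
        if len(dmps) >= 2:
            c1, s1 = comethylation_structure(meth1, dmps.probe_ids)
            c2, s2 = comethylation_structure(meth2, dmps.probe_ids)
            comp = compare_structures(c1, c2, seed=config.seed)
            temporal["comethylation_birth"] = s1
            temporal["comethylation_age7"] = s2
            temporal["structure_similarity"] = comp
        report["stages"]["temporal"] = temporal

    # ---- stage: risk score + exposure screen -----------------------------
    if len(dmps) == 0:
        report["stages"]["mrs"] = {"skipped": "no DMPs at birth"}
        report["stages"]["mediation"] = {"skipped": "no DMPs at birth"}
        _finalize(report, outdir)
        return report

    score_full = compute_mrs(meth1, dmps, variant="full")
    reduced, mqtl_report = exclude_mqtl_probes(dmps, mqtl_table)
    mrs_stage = {"n_dmps": len(dmps), "mqtl_excluded": mqtl_report}
    if len(reduced):
        score_red = compute_mrs(meth1, reduced, variant="mqtl_excluded")
        r_fr = float(np.corrcoef(score_full.scores, score_red.scores)[0, 1])
        mrs_stage["full_vs_reduced_r"] = r_fr
        pd.DataFrame({"sample_id": score_full.scores.index,
                      "score_full": score_full.scores.to_numpy(),
                      "score_mqtl_excluded": score_red.scores.to_numpy()}
                     ).to_csv(outdir / "risk_scores.csv", index=False)
    exposures = cohort[list(EXPOSURE_COLUMNS)]
    screen = screen_exposures(score_full, outcome, exposures)
    screen.to_csv(outdir / "exposure_screen.csv", index=False)
    mrs_stage["screen"] = screen.to_dict(orient="records")
    try:
        onset = onset_correlation(score_full, cohort)
        mrs_stage["onset"] = onset.to_dict(orient="records")
    except (KeyError, ValueError) as exc:
        mrs_stage["onset"] = {"skipped": str(exc)}
    report["stages"]["mrs"] = mrs_stage

    # ---- stage: mediation -------------------------------------------------
    hits = screen[(screen["variable"] == "dnam_risk")
                  & (screen["q"] < config.screen_q)]
    if hits.empty:
        report["stages"]["mediation"] = {
            "skipped": "no exposure passed the screen"}
        _finalize(report, outdir)
        return report
    med_exposures = exposures[list(hits["exposure"])]
    fit = fit_path_model(med_exposures, score_full.scores, outcome)
    fit = bootstrap_ci(med_exposures, score_full.scores, outcome,
                       B=config.bootstrap_B, seed=config.seed, fit=fit)
    per_sub = per_substance_mediation(med_exposures, score_full.scores,
                                      first_order)
    report["stages"]["mediation"] = {
        "screened_exposures": list(hits["exposure"]),
        "model": fit.summary(),
        "per_substance": {k: v.summary() for k, v in per_sub.items()},
    }
    with open(outdir / "mediation.json", "w") as fh:
        json.dump(report["stages"]["mediation"], fh, indent=1, default=str)

    _finalize(report, outdir)
    return report


def _finalize(report: dict, outdir: Path) -> None:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
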