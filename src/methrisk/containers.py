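"""In-memory containers shared across the pipeline.

The central object is :class:`MethylomeMatrix` — a samples x probes matrix of
methylation beta values (methylated signal / total signal, open interval
(0, 1)) for one timepoint, carrying a BED-like probe annotation. Phenotypes
travel as a plain :class:`pandas.DataFrame` (one row per sample), reference
signatures as :class:`ReferencePanel`, and simulation truth as
:class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ("chrom", "pos", "probe_id", "gene",
                      "cross_reactive", "control_probe", "snp_at_sbe_maf_gt_5")


@dataclass
class MethylomeMatrix:
    """Beta-value matrix for one timepoint plus probe annotation.

    Parameters
    ----------
    beta
        DataFrame of beta values, samples in rows (index = sample ids),
        probes in columns (columns = probe ids). All values in (0, 1).
    annotation
        DataFrame indexed by probe id with columns ``chrom`` (chromosome
        label), ``pos`` (1-based bp position), ``gene`` (may be empty) and
        the three boolean QC flags ``cross_reactive``, ``control_probe``
        and ``snp_at_sbe_maf_gt_5``.
    timepoint
        Free-form label, e.g. ``"birth"`` or ``"age7"``.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.beta.columns.duplicated().any():
            raise ValueError("duplicate probe ids in beta matrix")
        missing = self.beta.columns.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"probes missing from annotation: {list(missing[:5])} ...")

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    def validate(self) -> None:
        """Raise if beta values stray outside (0, 1) or contain NaN."""
        vals = self.beta.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("beta matrix contains NaN")
        if (vals <= 0).any() or (vals >= 1).any():
            raise ValueError("beta values must lie strictly inside (0, 1)")

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylomeMatrix":
        probe_ids = list(probe_ids)
        missing = [p for p in probe_ids if p not in self.beta.columns]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return MethylomeMatrix(
            beta=self.beta.loc[:, probe_ids],
            annotation=self.annotation.loc[probe_ids],
            timepoint=self.timepoint,
        )


@dataclass
class ReferencePanel:
    """Mean beta per (probe, cell type) for reference-based deconvolution."""

    signatures: pd.DataFrame  # index = probe ids, one column per cell type

    def __post_init__(self) -> None:
        if self.signatures.shape[1] < 2:
            raise ValueError("reference panel needs at least 2 cell types")
        vals = self.signatures.to_numpy()
        if (vals <= 0).any() or (vals >= 1).any():
            raise ValueError("reference betas must lie strictly inside (0, 1)")

    @property
    def probe_ids(self) -> pd.Index:
        return self.signatures.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.signatures.columns)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (the recovery oracle).

    Effects are stored on the scale at which they were applied — the
    logit(beta) scale for all methylation effects.
    """

    dmp_ids: list[str]
    dmp_effects: dict[str, float]                    # probe -> liability effect
    mqtl_probe_ids: list[str]
    mqtl_effects: dict[str, float]                   # probe -> per-allele shift
    exposure_probe_ids: dict[str, list[str]]         # exposure -> probes
    exposure_probe_effects: dict[str, float]         # exposure -> effect size
    cell_proportions_t1: pd.DataFrame
    cell_proportions_t2: pd.DataFrame
    liability: pd.Series                             # true latent L per sample
    first_order_factors: pd.DataFrame                # tobacco/cannabis/alcohol
    factor_loadings_first: list[float]
    factor_loadings_second: list[float]
    genotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_jsonable(self) -> dict[str, Any]:
        return {
            "dmp_ids": self.dmp_ids,
            "dmp_effects": self.dmp_effects,
            "mqtl_probe_ids": self.mqtl_probe_ids,
            "mqtl_effects": self.mqtl_effects,
            "exposure_probe_ids": self.exposure_probe_ids,
            "exposure_probe_effects": self.exposure_probe_effects,
            "cell_proportions_t1": self.cell_proportions_t1.to_dict(orient="index"),
            "cell_proportions_t2": self.cell_proportions_t2.to_dict(orient="index"),
            "liability": self.liability.to_dict(),
            "first_order_factors": self.first_order_factors.to_dict(orient="index"),
            "factor_loadings_first": list(self.factor_loadings_first),
            "factor_loadings_second": list(self.factor_loadings_second),
            "genotypes": self.genotypes.to_dict(orient="index"),
        }


@dataclass
class RiskScore:
    """Cumulative weighted DNA-methylation risk score.

    ``score_i = sum_j w_j * beta_ij`` exactly, where the weights are the
    discovery-stage standardized regression coefficients. The weight vector
    is frozen at construction; ``variant`` distinguishes the full score from
    the mQTL-excluded sensitivity variant.
    """

    scores: pd.Series                 # per sample
    weights: pd.Series                # probe -> weight
    variant: str = "full"
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def zscored(self) -> pd.Series:
        s = self.scores
        return (s - s.mean()) / s.std(ddof=1)
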