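"""Synthetic two-timepoint methylation cohorts with known planted structure.

The generator emulates the design of a prospective birth-cohort methylation
study: ~500 children with a 450k-style beta matrix at two timepoints (cord
blood at birth, whole blood at age 7), prenatal exposure scores, eight
adolescent substance-use indicators driven by a second-order liability
factor, reference cell-type mixtures, and a handful of mQTL-controlled
probes. Every planted quantity is returned in a :class:`GroundTruth` object
so downstream stages can be tested by parameter recovery.

All methylation effects act on the logit(beta) scale,

    logit(beta_ij) = mu_j + lambda_j * L_i + sum_e gamma_ej * E_ie
                     + delta_j * G_ij + sum_k c_kj * pi_ik + eps_ij ,

which keeps beta inside (0, 1) after the inverse-logit. ``L`` is the latent
substance-use liability, partially determined by the prenatal exposures so
that the exposure -> methylation -> substance-use mediation chain holds by
construction. At the second timepoint the residuals are regenerated with a
configurable cross-time correlation (low by default — neonatal methylation
is largely not preserved at age 7), while mQTL probes remain stable because
the genotype effect persists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import GroundTruth, MethylomeMatrix, ReferencePanel

SUBSTANCE_ITEMS = (
    "tobacco_14", "tobacco_16", "tobacco_18",
    "cannabis_14", "cannabis_16", "cannabis_18",
    "alcohol_16", "alcohol_18",
)
ITEM_FACTOR_INDEX = (0, 0, 0, 1, 1, 1, 2, 2)  # tobacco, cannabis, alcohol
FIRST_ORDER_FACTORS = ("tobacco", "cannabis", "alcohol")

EXPOSURE_COLUMNS = (
    "maternal_smoking", "maternal_alcohol", "life_events",
    "contextual_risks", "parental_risks", "interpersonal_risks",
)

_BETA_EPS = 1e-6


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the desk-scale analogue of the study design: 500
    samples x 20,000 probes, 65 differentially methylated probes (DMPs)
    loading on the liability factor, five of them under mQTL control, five
    reference cell types mixed from a Dirichlet, and essentially no
    persistence of liability effects at the second timepoint.
    """

    n_samples: int = 500
    n_probes: int = 20_000
    n_dmps: int = 65
    n_mqtl_dmps: int = 5
    # magnitude of the planted liability effect per unit L, logit-beta scale;
    # per-probe magnitudes are drawn uniformly within +-jitter of this value
    dmp_effect_sd: float = 0.105
    dmp_effect_jitter: float = 0.2
    # exposure -> (number of affected probes outside the DMP set, effect size)
    exposure_effects: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"maternal_smoking": (30, 0.22)})
    mqtl_effect: float = 0.6
    mqtl_maf: float = 0.3
    cross_time_autocorr: float = 0.10
    comethylation_block_corr: float = 0.30
    comethylation_block_size: int = 5
    # standardized loadings: 8 first-order (item on substance factor) and
    # 3 second-order (substance factor on liability), within the observed
    # 0.58-0.96 range for the first-order loadings
    factor_loadings: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.85, 0.90, 0.80, 0.80, 0.90, 0.85, 0.70, 0.75),
        (0.90, 0.85, 0.80),
    )
    cell_types: tuple[str, ...] = ("CD8T", "CD4T", "NK", "Bcell", "Mono")
    dirichlet_alpha: tuple[float, ...] = (6.0, 10.0, 2.0, 3.0, 4.0)
    noise_sd: float = 0.30
    seed: int = 0

    # exposure -> weight of the (standardized) exposure in the liability;
    # this is what makes mediation hold by construction
    liability_weights: dict[str, float] = field(
        default_factory=lambda: {"maternal_smoking": 0.30})
    # scale applied to liability and exposure effects at timepoint 2
    # (0 = the no-persistence scenario)
    t2_effect_scale: float = 0.0
    female_frac: float = 0.51
    smoking_prevalence: float = 0.18
    sex_effect: float = 0.10
    n_sex_probes: int = 200
    n_panel_probes: int = 200
    cell_contrast_sd: float = 1.5
    # QC flags planted in the annotation (all zero by default)
    n_cross_reactive: int = 0
    n_control_probes: int = 0
    n_snp_flagged: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_probes <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_dmps > self.n_probes:
            raise ValueError("n_dmps cannot exceed n_probes")
        if self.n_mqtl_dmps > self.n_dmps:
            raise ValueError("n_mqtl_dmps cannot exceed n_dmps")
        n_special = self.n_dmps + sum(c for c, _ in self.exposure_effects.values())
        if n_special > self.n_probes:
            raise ValueError(
                "planted DMP and exposure probe counts exceed n_probes")
        if len(self.cell_types) != len(self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha must match cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("Dirichlet alpha must be positive")
        first, second = self.factor_loadings
        if len(first) != len(SUBSTANCE_ITEMS) or len(second) != 3:
            raise ValueError("factor_loadings must be (8 first-order, 3 second-order)")
        if any(not np.isfinite(v) for v in (*first, *second)):
            raise ValueError("loadings must be finite")
        if any(abs(v) > 1 for v in (*first, *second)):
            raise ValueError(
                "standardized loadings > 1 imply a non-positive-definite "
                "indicator covariance")
        if not 0 <= self.cross_time_autocorr < 1:
            raise ValueError("cross_time_autocorr must be in [0, 1)")
        if not 0 <= self.comethylation_block_corr < 1:
            raise ValueError("comethylation_block_corr must be in [0, 1)")

    def null(self) -> "SimConfig":
        """Copy of the config with every planted effect switched off."""
        cfg = SimConfig(**asdict(self))
        cfg.dmp_effect_sd = 0.0
        cfg.mqtl_effect = 0.0
        cfg.exposure_effects = {}
        cfg.liability_weights = {}
        cfg.sex_effect = 0.0
        return cfg


def simulate_substance_items(
    liability: np.ndarray,
    loadings: tuple[Sequence[float], Sequence[float]],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate the 8 substance-use indicators from the two-level factor model.

    First-order factors (tobacco, cannabis, alcohol) load on the liability
    ``L`` with the second-order loadings; items load on their first-order
    factor with the first-order loadings. Loadings are standardized, so each
    factor and indicator has unit variance when ``L`` does. With all
    loadings equal to 1 the construction is deterministic and every item
    equals ``L``.

    Returns a DataFrame with the item columns plus the three true
    first-order factor scores (columns prefixed ``factor_``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    first, second = loadings
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != (len(SUBSTANCE_ITEMS),) or second.shape != (3,):
        raise ValueError("expected 8 first-order and 3 second-order loadings")
    L = np.asarray(liability, dtype=float)
    n = L.shape[0]

    disturb_sd = np.sqrt(np.clip(1.0 - second ** 2, 0.0, None))
    factors = second[None, :] * L[:, None] + disturb_sd[None, :] * rng.standard_normal((n, 3))

    uniq_sd = np.sqrt(np.clip(1.0 - first ** 2, 0.0, None))
    items = np.empty((n, len(SUBSTANCE_ITEMS)))
    for j, (lam, f_idx) in enumerate(zip(first, ITEM_FACTOR_INDEX)):
        items[:, j] = lam * factors[:, f_idx] + uniq_sd[j] * rng.standard_normal(n)

    out = pd.DataFrame(items, columns=list(SUBSTANCE_ITEMS))
    for k, name in enumerate(FIRST_ORDER_FACTORS):
        out[f"factor_{name}"] = factors[:, k]
    return out


def simulate_mediation_dataset(
    n: int,
    a: float = 0.4,
    b: float = 0.5,
    c_direct: float = 0.1,
    n_exposures: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simple planted mediation triple with unit-variance variables.

    ``exposure_1 -> mediator -> outcome`` with unstandardized paths ``a``
    and ``b`` and direct path ``c_direct``; additional exposures (if any)
    are independent noise predictors. Residual variances are chosen so the
    mediator and outcome have unit variance, hence the planted indirect
    effect is exactly ``a * b`` on both scales.
    """
    if abs(a) >= 1:
        raise ValueError("|a| must be < 1 for a unit-variance mediator")
    resid_m = np.sqrt(1.0 - a ** 2)
    var_y_explained = b ** 2 + c_direct ** 2 + 2 * a * b * c_direct
    if var_y_explained >= 1:
        raise ValueError("paths imply outcome variance above 1")
    resid_y = np.sqrt(1.0 - var_y_explained)

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_exposures))
    mediator = a * X[:, 0] + resid_m * rng.standard_normal(n)
    outcome = b * mediator + c_direct * X[:, 0] + resid_y * rng.standard_normal(n)

    data = pd.DataFrame({f"exposure_{k + 1}": X[:, k] for k in range(n_exposures)})
    data["mediator"] = mediator
    data["outcome"] = outcome
    truth = {"a": a, "b": b, "c_direct": c_direct, "indirect": a * b}
    return data, truth


def _make_annotation(cfg: SimConfig, rng: np.random.Generator,
                     special: dict[str, np.ndarray]) -> pd.DataFrame:
    m = cfg.n_probes
    probe_ids = np.array([f"cg{j:08d}" for j in range(1, m + 1)])
    chroms = np.array([str(c) for c in range(1, 23)] + ["X"])
    chrom_of = chroms[rng.integers(0, len(chroms), size=m)]
    pos = np.empty(m, dtype=np.int64)
    for c in chroms:
        mask = chrom_of == c
        k = int(mask.sum())
        if k:
            pos[mask] = np.sort(rng.choice(200_000_000, size=k, replace=False))
    gene = np.array([f"GENE{j % max(m // 3, 1):05d}" if rng.random() < 0.7 else ""
                     for j in range(m)], dtype=object)

    flags = {name: np.zeros(m, dtype=bool)
             for name in ("cross_reactive", "control_probe", "snp_at_sbe_maf_gt_5")}
    protected = np.zeros(m, dtype=bool)
    for idx in special.values():
        protected[idx] = True
    free = np.flatnonzero(~protected)
    counts = (cfg.n_cross_reactive, cfg.n_control_probes, cfg.n_snp_flagged)
    n_flag = sum(counts)
    if n_flag:
        if n_flag > free.size:
            raise ValueError("not enough unplanted probes to flag")
        chosen = rng.choice(free, size=n_flag, replace=False)
        off = 0
        for name, cnt in zip(flags, counts):
            flags[name][chosen[off:off + cnt]] = True
            off += cnt

    ann = pd.DataFrame({
        "chrom": chrom_of, "pos": pos, "gene": gene, **flags,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return ann


def _exposure_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    sex = (rng.random(n) < cfg.female_frac).astype(int)  # 1 = female
    smoking = (rng.random(n) < cfg.smoking_prevalence).astype(int)
    alcohol = rng.choice(4, size=n, p=(0.45, 0.30, 0.20, 0.05))
    # four cumulative stress scores share a mild common component
    common = rng.standard_normal(n)
    stress = {}
    for name in ("life_events", "contextual_risks", "parental_risks",
                 "interpersonal_risks"):
        stress[name] = np.sqrt(0.2) * common + np.sqrt(0.8) * rng.standard_normal(n)
    return pd.DataFrame({
        "sex": sex, "maternal_smoking": smoking, "maternal_alcohol": alcohol,
        **stress,
    }, index=pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample_id"))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def simulate_cohort(cfg: SimConfig) -> tuple[
        MethylomeMatrix, MethylomeMatrix, pd.DataFrame, GroundTruth,
        ReferencePanel, pd.DataFrame]:
    """Generate one synthetic two-timepoint cohort.

    Returns ``(methylome@t1, methylome@t2, cohort_table, ground_truth,
    reference_panel, mqtl_table)``. The same config (including seed) yields
    byte-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_probes

    # --- index sets: DMPs, mQTL subset, exposure probes, panel probes -----
    order = rng.permutation(m)
    cursor = 0
    dmp_idx = np.sort(order[cursor:cursor + cfg.n_dmps]); cursor += cfg.n_dmps
    mqtl_idx = np.sort(rng.choice(dmp_idx, size=cfg.n_mqtl_dmps, replace=False)) \
        if cfg.n_mqtl_dmps else np.array([], dtype=int)
    exposure_idx: dict[str, np.ndarray] = {}
    for exp_name, (cnt, _eff) in cfg.exposure_effects.items():
        exposure_idx[exp_name] = np.sort(order[cursor:cursor + cnt]); cursor += cnt
    n_panel = min(cfg.n_panel_probes, m - cursor)
    panel_idx = np.sort(order[cursor:cursor + n_panel]); cursor += n_panel
    n_sexp = min(cfg.n_sex_probes, m - cursor)
    sex_idx = np.sort(order[cursor:cursor + n_sexp]); cursor += n_sexp

    special = {"dmp": dmp_idx, "panel": panel_idx}
    for k, v in exposure_idx.items():
        special[f"exp_{k}"] = v
    ann = _make_annotation(cfg, rng, special)
    probe_ids = ann.index.to_numpy()

    # --- sample-level variables ------------------------------------------
    cohort = _exposure_table(cfg, rng)
    sample_ids = cohort.index

    resid_var = 1.0
    L = np.zeros(n)
    for exp_name, w in cfg.liability_weights.items():
        L += w * _standardize(cohort[exp_name].to_numpy(dtype=float))
        resid_var -= w ** 2
    if resid_var <= 0:
        raise ValueError("liability_weights imply non-positive residual variance")
    L += np.sqrt(resid_var) * rng.standard_normal(n)

    items = simulate_substance_items(L, cfg.factor_loadings, rng)
    factors = items[[f"factor_{f}" for f in FIRST_ORDER_FACTORS]].to_numpy()
    cohort = pd.concat(
        [cohort, items[list(SUBSTANCE_ITEMS)].set_index(sample_ids)], axis=1)

    # onset ages among endorsers: later onset for lower liability
    onset_base = {"cigarette": (0.12, 14.5), "cannabis": (-0.49, 15.0),
                  "alcohol": (1.39, 13.5)}
    for sub, (intercept, base_age) in onset_base.items():
        endorse = rng.random(n) < expit(intercept + 0.8 * L)
        age = base_age - 0.472 * L + 1.5 * rng.standard_normal(n)
        age = np.clip(np.round(age, 1), 10.0, 18.0)
        age[~endorse] = np.nan
        cohort[f"endorsed_{sub}"] = endorse.astype(int)
        cohort[f"onset_age_{sub}"] = age

    # --- probe-level parameters ------------------------------------------
    mu = np.empty(m)
    kind = rng.random(m)
    mu[kind < 0.4] = rng.normal(-2.5, 0.5, size=int((kind < 0.4).sum()))
    mid = (kind >= 0.4) & (kind < 0.8)
    mu[mid] = rng.normal(2.5, 0.5, size=int(mid.sum()))
    mu[kind >= 0.8] = rng.normal(0.0, 1.0, size=int((kind >= 0.8).sum()))
    # planted-effect and panel probes sit in the dynamic mid-range
    for idx in (dmp_idx, panel_idx, *exposure_idx.values(), sex_idx):
        if len(idx):
            mu[idx] = rng.normal(0.0, 0.5, size=len(idx))

    lam = np.zeros(m)
    if cfg.n_dmps:
        signs = np.where(np.arange(cfg.n_dmps) % 2 == 0, -1.0, 1.0)
        mags = cfg.dmp_effect_sd * rng.uniform(
            1 - cfg.dmp_effect_jitter, 1 + cfg.dmp_effect_jitter,
            size=cfg.n_dmps)
        lam[dmp_idx] = signs * mags

    gamma = {}
    for exp_name, (_cnt, eff) in cfg.exposure_effects.items():
        idx = exposure_idx[exp_name]
        g = np.zeros(m)
        g[idx] = eff * np.where(rng.random(len(idx)) < 0.5, -1.0, 1.0)
        gamma[exp_name] = g

    delta = np.zeros(m)
    genotypes = np.zeros((n, len(mqtl_idx)))
    if len(mqtl_idx):
        delta[mqtl_idx] = cfg.mqtl_effect * np.where(
            rng.random(len(mqtl_idx)) < 0.5, -1.0, 1.0)
        genotypes = rng.binomial(2, cfg.mqtl_maf, size=(n, len(mqtl_idx))).astype(float)

    sex_beta = np.zeros(m)
    if len(sex_idx):
        sex_beta[sex_idx] = cfg.sex_effect * np.where(
            rng.random(len(sex_idx)) < 0.5, -1.0, 1.0)

    cell_contrast = np.zeros((len(cfg.cell_types), m))
    if len(panel_idx):
        raw = rng.normal(0.0, cfg.cell_contrast_sd,
                         size=(len(cfg.cell_types), len(panel_idx)))
        cell_contrast[:, panel_idx] = raw - raw.mean(axis=0, keepdims=True)

    # co-methylation blocks over the DMP set (same assignment both timepoints)
    block_of = None
    if cfg.n_dmps and cfg.comethylation_block_corr > 0:
        block_of_dmp = np.arange(cfg.n_dmps) // cfg.comethylation_block_size
        block_of = np.full(m, -1, dtype=int)
        block_of[dmp_idx] = block_of_dmp

    def residuals(generator: np.random.Generator) -> np.ndarray:
        eps = generator.standard_normal((n, m))
        if block_of is not None:
            rho = cfg.comethylation_block_corr
            n_blocks = int(block_of[dmp_idx].max()) + 1
            shared = generator.standard_normal((n, n_blocks))
            sel = dmp_idx
            eps[:, sel] = (np.sqrt(rho) * shared[:, block_of[sel]]
                           + np.sqrt(1 - rho) * eps[:, sel])
        return cfg.noise_sd * eps

    pi1 = rng.dirichlet(cfg.dirichlet_alpha, size=n)
    pi2 = rng.dirichlet(cfg.dirichlet_alpha, size=n)
    eps1 = residuals(rng)
    eps2_fresh = residuals(rng)
    rho_t = cfg.cross_time_autocorr
    eps2 = rho_t * eps1 + np.sqrt(1 - rho_t ** 2) * eps2_fresh

    sex_vec = cohort["sex"].to_numpy(dtype=float)

    def assemble(pi: np.ndarray, eps: np.ndarray, effect_scale: float) -> np.ndarray:
        lg = np.tile(mu, (n, 1))
        lg += effect_scale * np.outer(L, lam)
        for exp_name, g in gamma.items():
            z = _standardize(cohort[exp_name].to_numpy(dtype=float))
            lg += effect_scale * np.outer(z, g)
        if len(mqtl_idx):
            lg[:, mqtl_idx] += genotypes * delta[mqtl_idx][None, :]
        lg += np.outer(sex_vec - sex_vec.mean(), sex_beta)
        lg += pi @ cell_contrast
        lg += eps
        return lg

    beta1 = np.clip(expit(assemble(pi1, eps1, 1.0)), _BETA_EPS, 1 - _BETA_EPS)
    beta2 = np.clip(expit(assemble(pi2, eps2, cfg.t2_effect_scale)),
                    _BETA_EPS, 1 - _BETA_EPS)

    meth1 = MethylomeMatrix(
        beta=pd.DataFrame(beta1, index=sample_ids, columns=probe_ids),
        annotation=ann, timepoint="birth")
    meth2 = MethylomeMatrix(
        beta=pd.DataFrame(beta2, index=sample_ids, columns=probe_ids),
        annotation=ann, timepoint="age7")

    panel_probes = probe_ids[panel_idx]
    panel = ReferencePanel(signatures=pd.DataFrame(
        np.clip(expit(mu[panel_idx][:, None] + cell_contrast[:, panel_idx].T),
                _BETA_EPS, 1 - _BETA_EPS),
        index=pd.Index(panel_probes, name="probe_id"),
        columns=list(cfg.cell_types)))

    mqtl_probes = probe_ids[mqtl_idx]
    mqtl_table = pd.DataFrame({
        "probe_id": mqtl_probes,
        "snp_id": [f"rs{900000 + j}" for j in range(len(mqtl_probes))],
        "type": ["trans" if (j + 1) % 5 == 0 else "cis"
                 for j in range(len(mqtl_probes))],
    })

    truth = GroundTruth(
        dmp_ids=list(probe_ids[dmp_idx]),
        dmp_effects={probe_ids[j]: float(lam[j]) for j in dmp_idx},
        mqtl_probe_ids=list(mqtl_probes),
        mqtl_effects={probe_ids[j]: float(delta[j]) for j in mqtl_idx},
        exposure_probe_ids={k: list(probe_ids[v]) for k, v in exposure_idx.items()},
        exposure_probe_effects={k: float(eff) for k, (_c, eff)
                                in cfg.exposure_effects.items()},
        cell_proportions_t1=pd.DataFrame(pi1, index=sample_ids,
                                         columns=list(cfg.cell_types)),
        cell_proportions_t2=pd.DataFrame(pi2, index=sample_ids,
                                         columns=list(cfg.cell_types)),
        liability=pd.Series(L, index=sample_ids, name="liability"),
        first_order_factors=pd.DataFrame(
            factors, index=sample_ids, columns=list(FIRST_ORDER_FACTORS)),
        factor_loadings_first=list(cfg.factor_loadings[0]),
        factor_loadings_second=list(cfg.factor_loadings[1]),
        genotypes=pd.DataFrame(genotypes, index=sample_ids, columns=list(mqtl_probes)),
    )
    return meth1, meth2, cohort, truth, panel, mqtl_table
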