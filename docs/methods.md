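# Methods

## The synthetic cohort generator

`methrisk.simulate.simulate_cohort` emulates a prospective two-timepoint
methylation study at desk scale. All methylation effects act on the
logit(beta) scale,

    logit(beta_ij) = mu_j + lambda_j L_i + sum_e gamma_ej E_ie
                     + delta_j G_ij + sum_k c_kj pi_ik + eps_ij,

with Gaussian residuals, so the inverse logit keeps beta strictly inside
(0, 1). Components:

- **Baseline means** `mu_j`: a bimodal mixture (modes at logit ±2.5, i.e.
  beta ≈ 0.08/0.92, plus a mid-range component), matching the bimodal
  post-QC distribution of 450k arrays. Probes carrying planted effects or
  cell-type contrasts are placed in the dynamic mid-range.
- **Liability effects**: `n_dmps` probes (default 65) load on the latent
  liability `L` with magnitude `dmp_effect_sd` (default 0.105 logit units,
  ±20% per-probe jitter) and alternating signs, giving roughly the 33/32
  hypo/hyper split of the motivating study. With residual SD 0.30 this
  calibrates the standardized discovery coefficients to ≈ 0.31 — inside the
  0.27–0.34 range the study reported — as verified by the Monte-Carlo
  oracle test.
- **Residual SD** `noise_sd = 0.30` logit units, equivalent to M-value SDs
  of ≈ 0.4, the upper-middle of typical post-QC probe variability. Larger
  values make beta-scale residuals at extreme-mean probes visibly skewed,
  which (correctly) degrades the far-tail calibration of probe-wise OLS
  t-tests.
- **Exposures and mediation by construction**: the liability is
  `L = 0.30·z(smoking) + sqrt(1−0.09)·u`; prenatal smoking additionally
  shifts 30 non-DMP probes by 0.22 logit units (the biological-validation
  signal). Because DMPs load on `L` and `L` depends on smoking, the
  exposure → methylation-score → substance-use indirect path exists by
  construction, while the four stress scores (mild common factor, r ≈ 0.2)
  and maternal alcohol stay null.
- **mQTLs**: a subset of DMPs (default 5) receives a per-allele shift of
  0.6 logit units with Hardy–Weinberg genotypes at MAF 0.3. The genotype
  persists at the second timepoint, so these probes are temporally stable
  while everything else decays.
- **Second timepoint**: effects are scaled by `t2_effect_scale`
  (default 0 — the no-persistence scenario); residuals are regenerated with
  correlation `cross_time_autocorr` (default 0.10) to the birth residuals,
  and cell mixtures are redrawn. Co-methylation is modelled as
  equicorrelated residual blocks of 5 DMPs (rho = 0.30) with the same block
  assignment at both timepoints, so the within-time intercorrelation
  pattern persists even though per-probe autocorrelation is low.
- **Cell composition**: Dirichlet mixtures over five leukocyte types
  (alpha = 6, 10, 2, 3, 4) act on 200 panel probes through cell-specific
  logit contrasts (SD 1.5); the reference panel stores the noiseless pure
  signatures. Mixing is linear on the logit scale while the deconvolution
  projects on the beta scale; the inverse-logit is close enough to linear
  over the panel's range that recovery correlations exceed 0.96 at
  `noise_sd ≤ 0.2`.
- **Substance-use items**: standardized two-level factor model — first-order
  loadings (0.85, 0.90, 0.80, 0.80, 0.90, 0.85, 0.70, 0.75), second-order
  (0.90, 0.85, 0.80), all within the 0.58–0.96 range the study printed.
  Ordinal frequency items are simulated (and analyzed) as continuous.
- **Onset ages** exist only for endorsers (endorsement probability rises
  with `L`); the planted liability–onset slope gives r ≈ −0.27 within
  endorser subgroups after range restriction.

What the generator does *not* emulate: IDAT intensities, normalization and
batch artefacts, probe-level missingness, realistic linkage structure for
the mQTL genotypes, measurement invariance violations, or informative
dropout. Passing recovery tests therefore demonstrates correctness of the
estimators under the generative model, not robustness to those real-data
complications.

## CFA

Maximum-likelihood discrepancy `F_ML` minimized by L-BFGS-B over free
parameters (marker loadings fixed to 1 for every factor including the
second-order factor; variances bounded below at 1e-8), `ftol` 1e-12, up to
4 jittered restarts. `chi2 = (N−1) F_ML`; baseline (independence) model in
closed form; CFI/TLI by the standard formulas; RMSEA with the N−1
convention (at N = 244 the N and N−1 conventions round identically).
RMSEA CI bounds invert the noncentral chi-square CDF by Brent root-finding
on the noncentrality. Heywood solutions are flagged (`admissible=False`),
not raised. Scoring is the regression method with a pseudo-inverse so
degenerate (singular-Sigma) models still score; the second-order score is
standardized. The model is fitted to complete cases only.

Our identification yields df = 17 for the 8-indicator model; the published
fit statistics we re-use in worked examples carry their own df and are used
as printed.

## EWAS

Methylation is the regression response, the phenotype the predictor (the
convention of probe-wise linear-model EWAS tools), complete cases, OLS with
classical SEs, two-sided t tests on n−k residual df. The standardized
coefficient `b·SD(x)/SD(y)` is a correlation-scale quantity comparable to
published Std B values. Zero-variance probes are emitted flagged with
missing p/q. BH is implemented directly (step-up with optional `m_total`
larger than the vector being adjusted, needed for the published-table
worked example) and property-tested against brute-force enumeration.

A type-I-error study (100 null cohorts, n = 300, 5,000 probes) checks
per-cohort KS uniformity and the family-wise BH discovery rate. Under the
global null the discovery rate is ≈ 0.05 (measured 25/500 cohorts across
ablations); the acceptance test asserts consistency with the 0.06 bound by
an exact one-sided binomial criterion, since a hard count over 100
replicates would fail ~15% of the time purely by sampling error at the
true rate.

## DMR calling

The spatially-correlated caller follows the comb-p construction. Probit
z-scores use `z = Phi^{-1}(1−p)` with p clipped to [1e-300, 1−1e-16]. The
ACF uses left-open right-closed 50-bp bins to 500 bp; correlations are
clipped to [0, 1). Smoothing combines probes within window/2 on either
side, so pairwise distances span the full ACF range. Regions are maximal
sub-threshold runs merged across gaps ≤ 500 bp, never across chromosomes,
0-based half-open (single probes span [pos, pos+1)). Region p combines the
*raw* p-values with the ACF; the Šidák exponent uses the union footprint of
±window/2 around the track's probes (the comb-p convention is ambiguous;
this choice is configurable). Single-probe regions are legitimate calls;
reports additionally count multi-probe regions, the field's working notion
of a DMR — on planted cohorts the liability probes are spatially isolated,
so that count is 0.

## Cell deconvolution

Per-sample constrained projection: NNLS (Lawson–Hanson) when the sum
constraint is slack; when it binds (or under `sum_eq_1`), an exact
support-enumeration solve of the equality-constrained KKT system — the
optimum's support satisfies the restricted stationarity conditions, so
enumerating the ≤ 2^K supports (K = number of cell types, small) and
keeping the best feasible candidate is exact. Default constraint is
`sum ≤ 1` (the constrained projection does not force the simplex);
estimates are used raw, not re-normalized, as covariates.

## Risk score, screen, onset

The score is the exact weighted sum of raw beta values with discovery
standardized coefficients as weights — weights are frozen at construction
and the score carries its provenance (timepoint, q threshold) to discourage
train/test leakage. The mQTL-excluded variant removes DMPs present in the
static mQTL lookup (cis/trans split reported). The exposure screen computes
Pearson r with BH over the 6-exposure family separately for the score row
and the outcome row. Onset correlations condition on the endorsement masks
and report (r, p, n) per substance.

## Mediation

The recursive path model is estimated by its OLS equivalence: mediator on
exposures (a-paths), outcome on mediator + exposures (b, c′). Mediator and
outcome are z-scored by default (coefficients comparable across scores
built on different probe sets); unstandardized and fully standardized
coefficients are both reported, and `indirect_k = a_k·b` exactly. Inference:
case-resampling bootstrap with percentile CIs (bias-corrected behind a
flag), seeded `default_rng` so CIs are bit-reproducible; singular resamples
are redrawn and counted; Wald/Sobel p-values are reported alongside. No
sex/cell covariates enter the path model by default (they can be appended
to the exposure block). Winsorization replaces values beyond mean ± 3 SD
(pre-modification SD) with the boundary.

Bootstrap percentile CIs at n = 500, B = 500 cover the planted indirect
effect at ≈ 95–97% in the acceptance study — the usual mild conservatism of
percentile intervals for product parameters.

## Pipeline and problem sizes

`run_pipeline` executes the stages in study order, persists per-stage
artifacts, and gates the mediation stage on both q < 0.05 filters (no DMPs
or no screened exposures → recorded skip). All randomness flows from the
config seed. Default desk scale is 500 × 20,000 (a full 413,510-probe run
is configuration, not code); the acceptance chain uses 2,000 × 10,000 so
that ≥ 60/65 DMP recovery is a sharp expectation, the type-I study uses
100 × (300 × 5,000) cohorts, and the bootstrap-coverage study 200
replicates of n = 500 with B = 500 — sizes chosen so each study estimates
its quantity with useful precision while the whole suite stays fast.

## Known limitations

- Ordinal items treated as continuous in both generator and CFA (no
  categorical/WLSMV estimation).
- OLS on bounded beta values has mildly inflated far-tail error rates when
  residual variability is large at extreme-mean probes; the engine reports
  what OLS reports, as the motivating analysis did.
- X-chromosome probes receive no special handling beyond the sex covariate.
- The Šidák footprint convention and the comb-p max_gap/window semantics
  follow the two published defaults (1e-4, 500 bp) plus documented choices;
  other comb-p implementations may differ in detail.
- semopy/lavaan cross-checks are not part of the suite; CFA correctness is
  established against exact population-covariance constructions and
  generator ground truth instead.
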