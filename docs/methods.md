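# Methods

## Overview

`glymph-alps` is a synthetic test-bed for the DTI-ALPS (diffusion
tensor image analysis along the perivascular space) biomarker and the
cohort statistics typically built around it.  It has two halves:

1. an **imaging chain** — a periventricular diffusion-MRI phantom with
   a controllable perivascular diffusivity excess, a per-voxel tensor
   fit, and the ALPS-index ROI measurement; and
2. a **cohort chain** — a subject-table generator for a three-group
   observational design (healthy controls, possible idiopathic
   REM-sleep behaviour disorder, Parkinson's disease) and the full
   statistical battery such a study runs (group contrasts, inter-rater
   ICC, propensity matching, Spearman families with FDR control,
   clinical subgrouping, logistic discrimination, longitudinal rates of
   change).

Everything is seeded and reproducible; all randomness in the pipeline
flows from one master seed through named substreams.

## The phantom

The ALPS method rests on a geometric coincidence at the body of the
lateral ventricle: the medullary perivascular spaces run right–left
(x), perpendicular to both the projection fibres (superior–inferior, z)
and the association fibres (anterior–posterior, y).  The phantom models
exactly this and nothing more: axis-aligned boxes for ventricle,
projection, association and subcortical fibre regions inside a
32×32×16 slab of 2-mm isotropic voxels (configurable), all placed in
the left hemisphere, the side on which measurements are taken by
convention in right-handed cohorts.

Fibre tensors are axis-aligned and diagonal with eigenvalues
(1.7, 0.3, 0.3)×10⁻³ mm²/s (parallel, radial, radial) — typical
white-matter values; the ventricle is isotropic at the free-water
3.0×10⁻³ mm²/s, background isotropic at 0.8×10⁻³ mm²/s.  Perivascular
flux is modelled as a non-negative additive excess `pvs_weight` on the
Dxx element in the projection and association regions only.  This is a
deliberately phenomenological construct: it produces exactly the
signature the ALPS index is designed to detect (extra x-diffusivity
where the PVS crosses the fibres) without simulating fluid dynamics.

Signals follow the mono-exponential tensor model
S = S₀·exp(−b·gᵀDg) for a 30-direction, b = 1000 s/mm², single-b₀
scheme.  Directions come from a deterministic spherical Fibonacci
spiral on the hemisphere (g and −g probe the same axis), giving
reproducible, nearly uniform angular coverage in place of an
unspecified vendor table.  Noise is Rician, built from two Gaussian
quadrature channels: S_noisy = √((S+ε₁)² + ε₂²), ε ~ N(0, σ²).  The
default σ = S₀/40 is an SNR-40 choice typical of 3-T echo-planar DTI;
it is a package default, configurable per run.  With σ = 0 the model
signal is exact, which the round-trip tests exploit.

### What the phantom does not emulate

No EPI distortion, motion, eddy currents, partial voluming, CSF
pulsation or anatomical curvature.  Passing tests therefore show the
*estimator chain* is correct (fit → maps → ROI → index), not that the
index is robust to real-world acquisition artefacts.

## Tensor fitting and axis diffusivities

The fit is log-linear least squares on ln S with the design row
(1, −b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz, −2b·gy·gz); the
default `wls` variant re-weights by the squared predicted signal for a
single iteration, the standard variance correction for log-transformed
magnitude data.  Non-positive signals are clamped to the smallest
positive value in the volume before the log and flagged; voxels with
non-positive b₀ signal are masked.  Negative eigenvalues are clamped to
10⁻⁷ mm²/s before FA, with the clamp count logged and reported.

A point that matters for the ALPS semantics: Dx, Dy, Dz are the
**diagonal elements of the tensor in the scanner frame** — the apparent
diffusivity along each laboratory axis — not eigenvalue projections.
The ALPS ratio is defined on those axis diffusivities.

## The ALPS index

Two 5-mm discs are placed on a single axial slice at the ventricle
body, one in the projection-fibre area and one in the association-fibre
area.  Voxel membership is centre-in-disc (a voxel belongs iff its
centre lies within diameter/2 of the ROI centre); there is no
partial-volume weighting, which keeps the mask enumerable and testable
by brute force.  The index is

    ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)

The denominator uses only Dyproj and Dzassoc: in each fibre population
the diffusivity perpendicular to both the fibre axis and the PVS
direction.  Dyassoc and Dzproj (parallel to the fibres) are recorded
for audit but excluded from the ratio.  With `pvs_weight` = 0 and equal
radial eigenvalues the noiseless index is exactly 1; it is strictly
increasing in `pvs_weight` and invariant to a global rescaling of the
diffusivity maps.

Slice selection is a passthrough: phantoms carry a declared slice, real
data require a manually configured index.  Automated medullary-vein or
ventricle detection is out of scope.  The two-rater protocol is
simulated by jittering the ROI centres (default one voxel, within the
same fibre region), which on a uniform phantom reproduces identical
measurements and an ICC of 1.

## The cohort generator

The generator's defaults *are* the study conditions: group sizes
129/119/168 (HC/piRBD/PD), per-group means and SDs for age, education,
the cognitive (MMSE, MoCA), affective (HAMD, HAMA), sleep (RBDQ-HK
total and factor II, ESS, PDSS) and motor (UPDRS III, H–Y, LED)
instruments, binary history frequencies, and group ALPS means
1.31/1.25/1.20 (SD 0.17).  Instruments not administered in a group are
missing by design (ESS/PDSS in piRBD; staging/medication outside PD),
and the RBDQ-HK scales are present for a random 88-patient subset of
the PD group, so complete-case handling is exercised everywhere.

Continuous variables are drawn through a Gaussian copula, then
transformed to their normal marginals, truncated to instrument ranges
and rounded where instruments are integer-valued (H–Y on a 0.5 grid).
Because the associations of interest are reported as Spearman
correlations, copula entries are specified as target Spearman ρₛ and
mapped to the latent Pearson ρ = 2·sin(πρₛ/6).  Defaults induce the
ALPS–severity associations (piRBD: ALPS~RBDQ-HK II at ρₛ = −0.236; PD:
ALPS~UPDRS III at ρₛ = −0.303) plus intra-instrument consistency
(total~factor II at 0.8, MMSE~MoCA at 0.7).  A single group-level
parameter cannot reproduce several subgroup-specific correlations
simultaneously; the PD default uses the largest subgroup's value and
all entries are configurable.

Truncation and rounding shift some means slightly: a Normal(21.64,
12.37) clipped at 0 has mean ≈21.84, so severity-score recovery is
asserted at the 2% level while the unclipped ALPS means recover to
±0.005.  With every SD set to 0 the generator degenerates to exact
group means (no truncation or rounding applied), a contract the tests
rely on.

### Longitudinal arm

Fifty baseline/follow-up PD pairs.  The follow-up interval is a
truncated normal with SD 13.23 months and a floor at the 12-month
eligibility criterion; its location is calibrated numerically so the
*post-truncation* mean equals the reported 23.36 months (a naive
truncation of Normal(23.36, 13.23) at 12 would have mean ≈27.9).
Follow-up scores are correlated redraws, value_f = μ_f + σ_f·(ρ·z_b +
√(1−ρ²)·ε) with retest correlation ρ = 0.7 by default; age and disease
duration advance deterministically with the interval, and chronic
history flags are drawn once.  A retest correlation below 1 builds
regression to the mean into the change rates, which is why the
standardised slope of ΔALPS/T on baseline ALPS is negative in
expectation — the directional finding the longitudinal tests check.

## The statistical battery

- **Normality gate.** One-sample Kolmogorov–Smirnov against
  Normal(sample mean, sample SD); a group set is "normal" iff every
  group has p ≥ 0.05.  The gate selects ANOVA/t versus
  Kruskal–Wallis/Mann–Whitney, with the decision logged.  Which branch
  the original analyses used per variable is not reconstructible, so
  the gate is this package's explicit, deterministic policy.
- **Post hoc.** Pairwise contrasts with Bonferroni adjustment over the
  pair family (the post hoc correction method is a package choice,
  configurable).
- **ICC.** Two-way random-effects, absolute-agreement, average-measures
  ICC(2,k) from the classical ANOVA mean squares, with the F-based
  confidence interval (Satterthwaite df for the single-measures bounds,
  Spearman–Brown step-up); ICC(3,k) available by flag.  Verified to
  machine precision against an independent mean-squares oracle and
  against pingouin.
- **Propensity matching.** Logistic propensity model, 1:1 greedy
  nearest-neighbour without replacement on logit-PS, caliper
  0.2·SD(logit-PS), with a standardised-mean-difference balance report.
  Greedy matching cannot guarantee 100% pairing even on identical arms;
  it does guarantee no control is reused and that imbalance shrinks.
- **FDR.** Benjamini–Hochberg step-up, adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j
  capped at 1, applied within declared families.  On the five-test
  longitudinal family with raw {<0.001, 0.045, 0.040, 0.442, 0.332}
  this yields {<0.01, 0.075, 0.075, 0.442, 0.415} — the worked example
  frozen in the acceptance tests.
- **Subgrouping.** Early/late PD at H–Y ≤ 2.5; motor terciles at the
  input table's own UPDRS III mean ± SD; cognitive impairment at
  MMSE < 27 or MoCA < 24; symptomatic RBD at RBDQ-HK total > 17 or
  factor II > 7; daytime sleepiness at ESS ≥ 10 (inclusive).
- **Discrimination.** Maximum-likelihood logistic regression of
  PD = 1 versus everyone else (comparator configurable), Wald OR CIs,
  in-sample ROC with trapezoidal AUC, and a separation guard that
  aborts on coefficient divergence or non-convergence.
- **Rates of change.** Δ/T = (follow-up − baseline)/interval·100, in
  % of the raw scale per month; exactly antisymmetric; positive
  interval required.
- **Longitudinal regression.** OLS on z-standardised outcome and
  predictor (continuous covariates standardised, binary encoded 0/1),
  reporting the standardised coefficient; the raw-scale coefficient is
  also emitted.  Rank-deficient designs are an error, not a silent
  drop.

## Numerical and design choices

- b-values are treated as s/mm² throughout (the conventional DTI unit).
- Coordinates are RAS with x = right–left; "left hemisphere" means
  x below the volume midline, and ROI centres are validated against the
  hemisphere tag.
- WLS uses exactly one re-weighting iteration; on noiseless input it
  agrees with plain LLS to 10⁻⁹.
- Ties in Spearman use mid-ranks (scipy); p-values are two-tailed.
- Problem sizes in the test suite (32×32×16 phantom, 50–200 Monte-Carlo
  replicates, 1000-replicate type-I-error checks) were chosen so the
  Monte-Carlo error is comfortably below each asserted tolerance while
  the whole suite runs in well under a minute.

## Known limitations

- The phantom's uniform axis-aligned regions make ROI placement
  trivially stable; inter-rater ICC on real data reflects anatomical
  ambiguity the phantom does not contain.
- The cohort generator draws groups independently with normal
  (truncated/rounded) marginals; it does not model diagnostic
  misclassification of the piRBD screen, medication effects, dropout,
  or skewed/zero-inflated score distributions (e.g., UPDRS III in
  controls is near-degenerate at 0.58 ± 1.26 and is clipped at 0).
- Single-slice, left-hemisphere-only ROI logic; no bilateral averaging
  beyond a configuration flag, no standard-space registration.
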