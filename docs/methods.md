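# Methods

This note documents the models behind each pipeline stage, the numerical
choices that were genuinely open, what the synthetic generators do and do
not emulate, and the known limitations.

## Pressure–volume analysis (Ψ_TLP)

### Model

Bench drying yields paired (fresh mass, Ψ) observations. With relative
water content R = (fresh − dry)/(sat − dry), plant water relations
(Tyree–Hammel type analysis) predict two phases:

* turgid phase (R ≥ R_TLP): Ψ = Ψs(R) + Ψp(R), osmotic plus turgor
  pressure components;
* post-turgor-loss phase (R < R_TLP): Ψ = Ψs(R) = π₀/R, so the
  transform y = −1/Ψ is linear in x = 1 − R.

The turgor loss point is the junction: Ψ_TLP = π₀ / R_TLP, which is
always at least as negative as the full-turgor osmotic potential π₀.

### Estimation

The breakpoint is found by an exhaustive two-segment scan over the
ordered transformed data: every split leaving ≥ 4 points in the terminal
(dry) segment and ≥ 2 in the initial segment is evaluated, and the split
with the lowest summed residual sum of squares wins. Two numerical
choices matter:

1. **Residuals are scored on the Ψ scale, not the transformed scale.**
   Measurement noise is approximately additive on Ψ (pressure-chamber
   error), and the variance of −1/Ψ explodes as Ψ → 0: scoring on the
   transformed axes lets the near-saturation points dominate and drags
   the split toward the wet end by several tenths of an MPa even on
   noise-free data. Each candidate split is therefore scored by mapping
   the terminal line back through Ψ = −1/(c₀ + c₁x) and fitting the
   initial segment with a quadratic in Ψ itself.
2. **The breakpoint abscissa is refined between the two bracketing
   observations** as the intersection of the initial-segment quadratic
   with the extrapolated osmotic curve, so the estimate is not limited
   to the sampling grid. On noise-free synthetic curves this recovers
   Ψ_TLP to ≲ 2 × 10⁻⁵ MPa; at 0.05 MPa Ψ noise the mean absolute error
   is ≈ 0.04 MPa (12-point curves).

Observations with Ψ > −0.05 MPa are excluded from the transform (the
chamber cannot resolve such small tensions and −1/Ψ is unstable there),
as are oversaturation artifacts (RWC > 1, flagged). Data that are linear
over the whole transformed range (no captured turgor phase) are fitted
but flagged `no_curvature_detected`; a terminal segment whose −1/Ψ does
not decline with dehydration is a hard error, since no osmotic line can
produce it. Saturated mass defaults to the maximum observed fresh mass;
an extrapolation mode regresses mass on Ψ over the k = 4 wettest points
and takes the intercept at Ψ = 0, falling back (with a warning) when the
wet-region slope is non-positive.

## Vulnerability curves (Ψ12, Ψ50)

PLC = 100 (Kmax − Ki)/Kmax with Ki = J_V / (ΔP/ΔL). Negative PLC
(flushing raised Ki slightly above Kmax) is clipped to 0 and flagged.
Branches are accepted only if their two wrapped-leaf potentials differ
by strictly less than 0.20 MPa (an epsilon of 10⁻⁹ guards the boundary
against float representation); Ψ_stem is their mean.

The default model is the sigmoid PLC(Ψ) = 100/(1 + exp(a(Ψ − Ψ50))),
fit by bounded nonlinear least squares (trust-region reflective),
initialised at a = 1 MPa⁻¹ and Ψ50 at the observation nearest PLC = 50,
with perturbed restarts before declaring non-convergence. Fits require
≥ 6 accepted branches spanning ≥ 1.5 MPa — below that span the sigmoid
is unidentifiable. Curves are fitted per species × microhabitat on
pooled branches, not per individual; each branch is one dehydration
time point. A Weibull alternative (PLC = 100(1 − exp(−(−Ψ/b)^c))) is
available via `model="weibull"` for sensitivity analysis; its steepness
is reported as the local log-odds slope at Ψ50 so the two families are
comparable.

**Uncertainty.** Nonparametric case resampling of branches (default
n_boot = 1000, mandatory seed). The interval reported is the **basic
(reverse-percentile) interval** 2θ̂ − q_{97.5/2.5}: in calibration runs
at bench-scale sample sizes (30 branches, 5-point PLC noise, 200
replicate campaigns) the raw percentile interval covered the true Ψ50
in 89.0% of runs versus 91.5% for the basic interval, whose use is
justified by the near-symmetric estimator error distribution
(skew ≈ −0.06). Raw percentiles remain available via
`method="percentile"`. Replicates that fail to refit are dropped; more
than 20% dropped flags the interval as `ci_widened`.

Sapwood-specific conductivity divides Kmax by the functional sapwood
area (total cross-section minus non-conductive pith).

## Stomatal regulation (σ, hydroscape, HSM)

σ is the OLS slope of Ψ_MD on Ψ_PD. Choices:

* **OLS rather than standardized major axis**, because the isohydricity
  framework (Martínez-Vilalta type) is regression-based — Ψ_PD is the
  predictor, and the slope's interpretation (0 = strict isohydric,
  1 = strict anisohydric) assumes the regression form.
* **Technical replicates are averaged per individual × date before
  regression** to avoid pseudo-replication; the regression then pools
  all individual × date means within a species × microhabitat.
* Class labels use ±0.05 tolerance bands around σ = 0 and σ = 1, since
  exact equality never occurs on data. Negative slopes are flagged and
  reported, not suppressed.
* Fits require ≥ 5 pairs spanning ≥ 0.3 MPa of Ψ_PD.

The hydroscape is the triangle bounded by the regression line, the
Ψ_MD axis and the 1:1 line; with intercept Λ < 0 and σ < 1 its vertices
are (0,0), (0,Λ), (Λ/(1−σ), Λ/(1−σ)) and its area is Λ²/(2(1−σ)).
A trapezoid-rule twin (`hydroscape_numeric`) integrates the vertical gap
between the two lines and serves as a permanent internal oracle; the two
agree to < 10⁻⁶ MPa² over the valid domain (the integrand is linear, so
the trapezoid rule is exact up to rounding). For σ ≥ 1 or Λ ≥ 0 the
region is unbounded or empty; the area is reported as 0 with a flag
rather than raising, so multi-group pipelines do not abort.

Safety margins are plain differences, HSM12 = Ψ_min − Ψ12 and
HSM50 = Ψ_min − Ψ50, with Ψ_min the mean of foil-wrapped midday leaf
potentials at the end of the dry season. Negative margins are valid
results (operation beyond the embolism threshold), and
HSM50 − HSM12 = Ψ12 − Ψ50 > 0 holds for every converged fit.

## Anatomy (Dh) and leaf traits (LMA, PPI)

Dh = (ΣD⁴/N)^(1/4) per section; group values average the five replicate
sections per species × microhabitat, respecting the replication
structure rather than pooling vessels. Diameter distributions are
summarised by a Gaussian KDE (Silverman bandwidth — the densities are
descriptive, not inferential) on a grid extending four bandwidths past
the data so the density integrates to 1 within 10⁻³; fewer than 10
vessels falls back to a normalised histogram with a warning.

LMA = dry mass / leaf area with cm² → m² conversion. The variability
index PPI = (max − min)/max over the three microhabitat means uses
**magnitudes by default**: applied literally to negative-valued traits
(Ψ_TLP ≈ −2 MPa), the formula yields negative indices, and only the
magnitude reading produces the positive, bounded values the index is
meant to convey. A literal `mode="raw"` is retained for audit.
Microhabitat classes follow the elevation bands valley < 300 m ≤ slope
≤ 380 m < hilltop.

## Synthetic generators

Each generator is a pure function of a frozen parameter object with a
mandatory seed.

* **P–V**: the two-phase model above with linear turgor decline,
  Ψp(R) = −π₀(R − R_TLP)/(1 − R_TLP) — the minimal model consistent
  with classical P–V theory. Apoplastic fraction defaults to 0 and is
  exposed as a parameter. Default 12 observations per curve, R from 1.0
  down to R_TLP − 0.15, matching typical bench-drying sampling.
* **Vulnerability**: Ψ_stem evenly spread over (−6, −0.25) MPa, default
  30 branches; PLC from the sigmoid plus truncated Gaussian noise;
  (Ki, Kmax) back-computed so Ki/Kmax = 1 − PLC/100 holds exactly.
  A range that fails to bracket Ψ50 flags the series poorly constrained.
* **Drydown**: 5 individuals × 12 dates, Ψ_PD declining linearly over
  the campaign with a small per-individual offset, two replicate leaves
  per individual per date, Ψ_MD = Λ + σΨ_PD + ε.
* **Vessels**: lognormal mixture parametrised by component means/SDs;
  two separated components emulate dimorphic xylem.

Noise everywhere is additive Gaussian on the measured quantity,
truncated to the physical range ([0,100] for PLC, Ψ ≤ 0). Real
pressure-chamber and flow-meter error is not necessarily Gaussian, and
real drydowns are weather-driven rather than linear; passing recovery
tests therefore demonstrates estimator correctness under a clean
generative model, not robustness to every field artifact. The
generators make no attempt at mechanistic soil–plant–atmosphere
dynamics.

## Problem sizes and determinism

Recovery checks use 200 replicate campaigns for Ψ50 (with 500 bootstrap
refits each) and σ, and 100 for Ψ_TLP — sizes at which the reported
means are stable to well within the tolerances they are compared
against. All stochastic steps take explicit seeds; `hydrotraits run`
writes a run log with the config hash, seed and package version, and
identical inputs + seeds give identical output CSVs.

## Known limitations

* The TLP scan assumes the curve actually crosses turgor loss; curves
  truncated before the TLP are flagged, not rescued.
* The sigmoid and Weibull families cannot represent non-monotone or
  two-step vulnerability curves (e.g., strongly dimorphic xylem).
* σ and the hydroscape inherit OLS assumptions; errors-in-variables in
  Ψ_PD attenuate σ slightly at high measurement noise.
* PPI uses three microhabitat means only; it is undefined when any
  habitat is missing and intentionally not imputed.
* Group significance testing is out of scope; summaries report
  mean ± SD ± n so any standard test can be applied downstream.
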