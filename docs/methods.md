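# Methods

This note records the models, conventions and numerical choices behind
`rangeshift`, and what the synthetic experiments do and do not establish
about real data.

## Study design assumed by the pipeline

One *animal-year* (an individual within one winter) is the sampling unit.
Each animal-year has hourly fixes in projected meters over three
contiguous experimental phases — pre-closure, closure, post-closure —
with food access at the animal's *manipulated* feeding site (M) withdrawn
during closure and restored afterwards, while *alternate* managed sites
(A) stay open throughout. Raw phase lengths vary between animal-years
(field logistics), so every phase is truncated to a common 14-day window
before analysis: pre-closure and closure keep their final 14 days
(anchored at the phase end, removing initial excess), post-closure keeps
its first 14 days. Phase boundaries are half-open `[start, end)` in UTC.
Missing fixes are never interpolated; steps spanning a gap are flagged
and excluded from turning-angle and lag chains.

The onset of the pre-closure phase can be derived from the data as the
first re-visitation of the capture location after the post-capture
excursion (`detect_resettlement`); the radius defaults to the population
scale *l* and is exposed as an argument since no canonical value exists.

## The population scale l

*l* is the population mean hourly displacement over all retained 1-hour
steps, computed from the dataset at hand rather than hard-coded. It sets
the feeding-site buffer radius (working scale 1 × *l*) and, halved, the
kernel bandwidth. On the synthetic defaults *l* lands near 65 m; in the
field system emulated here it is ~61 m.

## Resource states and preference

Sites are buffered points; a fix is M if within the buffer of the
manipulated site, else A if within any alternate's buffer, else V
(matrix). Two conventions are deliberate:

- **closed disc**: distance ≤ buffer counts as inside;
- **precedence M > A** where buffers overlap (unstated in the field
  protocol; M-precedence is conservative for the headline contrast, the
  collapse of M-use during closure).

The manipulated site is identified per animal-year as the managed site
with the most pre-closure fixes within radius *l*; ties break to the
smaller mean distance, then lexicographic site id, making the assignment
deterministic. Preference h_FS is the proportion of truncated pre-closure
fixes classified M or A, recomputed per year for repeat individuals. The
buffer-sensitivity analysis recomputes h_FS at {0.5, 1, 1.5, 2, 3, 4} × *l*
and reports the across-animal IQR per scale; the working scale stays at
1 × *l* unless `auto_scale` is requested, keeping results comparable
across datasets. Animal-years with no pre-closure A-state are excluded
from the resource-use models (no usable contrast); the exclusion is
logged and can be disabled for a sensitivity rerun.

## Utilization distributions, areas, overlap

The UD per animal-year × phase is the average of isotropic Gaussian
kernels (sd = *l*/2) over the phase's fixes, evaluated at the centres of
a 10 m grid and renormalized to sum to one. The grid is the fix bounding
box padded by 4 bandwidths and snapped to the resolution lattice: 4σ
captures > 99.99% of each kernel's mass, so areas are insensitive to the
padding rule (verified by the refinement property: halving the cell size
moves the 95% area by < 2%).

Isopleth areas are cell-count based (no polygonization): cells ranked by
probability, smallest prefix reaching the level, area = count × cell
area in hectares. Density ties at the threshold make the *membership*
ambiguous but not the count, so the area is deterministic. 95% defines
the home range, 50% the core area; area(0.50) ≤ area(0.95) by
construction.

VI overlap re-evaluates both kernel sets on the union extent at the
common resolution (never interpolates a grid) and takes Σ min(p₁, p₂).
Analytic oracles pin the implementation: one kernel's 95% isopleth is a
disc of area πσ²(−2 ln 0.05), and two equal Gaussians offset by d overlap
by 2Φ(−d/2σ).

## Movement metrics

Steps are Euclidean displacements between successive fixes; the turning
angle is the signed heading change, wrapped to (−π, π], counterclockwise
positive. Zero-length steps have no heading; the previous non-zero
heading is carried forward so the next turn stays defined, and the turn
*at* the zero step is missing. For modelling, step length enters as
ln(max(s, 1 m)) and the absolute turning angle as logit(|θ|/π) with a
10⁻⁶ clamp at both ends: dividing by π is the only linear scaling that
maps the (−π, π] support onto (0, 1), and the clamp keeps the transform
total without affecting bulk estimates. The same clamp is used for logit
VI. Lagged step-length covariates (1, 2, 24 h) are aligned on the hourly
slot grid; rows with any missing lag are excluded from model tables, not
imputed. Lag covariates enter on the log scale, matching the response.

## Mixed models

All models use ML (not REML) with an animal-year random intercept:

- **LMMs** (statsmodels `MixedLM`) for log area, logit VI, log step
  length and φ; fixed effects Phase (reference pre-closure), h_FS, Sex
  (reference F), Phase:h_FS, Phase:Sex; the step-length model adds the
  three lag covariates. The overlap model replaces Phase by the contrast
  factor (reference pre/closure).
- **Binomial GLMMs** for the u_M, u_A, u_V series, fitted by
  Laplace-approximated ML written in this package (scalar random
  intercept per group; damped Newton inner loop for the conditional
  modes; L-BFGS-B over (β, log σ); SEs from the numerical Hessian).
  statsmodels offers no frequentist GLMM; this implementation was checked
  against the σ → 0 ordinary-logistic limit and parameter-recovery
  simulations, and reproduces reference mixed-logit fits to ~4 decimals
  on shared test data. Complete separation or non-convergence triggers a
  lightly ridge-penalized refit, flagged on the result. For u_V the
  pre-closure observations are excluded and closure is the Phase
  reference: h_FS is by definition one minus mean pre-closure V-use, so a
  pre-closure level would be circular.

Term p-values are likelihood-ratio tests of each term against the model
without it; main effects shielded by a retained interaction are not
tested (marginality). The fixed-effect structure is built progressively
(`build_model_sequence`) to check coefficient sign stability before
trusting the full model, and `drop_nonsignificant` performs backward
elimination at α = 0.05, never removing a main effect while one of its
interactions remains. LRT on ML fits is a deliberate, reproducible
choice; degrees-of-freedom approximations (Kenward–Roger, Satterthwaite)
would give slightly different p-values.

Variance explained uses variance partitioning: marginal
R² = σ²_f / (σ²_f + σ²_α + σ²_ε) with σ²_f the variance of the
fixed-effect predictor Xβ̂ over the data, conditional R² adds σ²_α to the
numerator; binomial-logit models use the distribution-specific residual
variance σ²_ε = π²/3. A grouping-sensitivity helper refits the final
model with animal-level (instead of animal-year) grouping and reports
per-term sign and significance agreement.

When the random-variance estimate hits the boundary, the ML solution
coincides with OLS; the LMM fitter falls back to that exact limit rather
than failing, and flags the singular variance.

## The synthetic experiment generator

The generator's purpose is to produce data with the statistical structure
the analysis assumes, with known ground truth. The field experiment
specifies no generative movement model, so the three-mode mover is an
explicit assumption — the simplest mechanism that produces all expected
response directions:

- **ATTEND**: fixes scattered around the target site (gamma steps, mean
  10 m); attendance ends per hour with probability 1/dwell (dwell 4 h).
- **FORAGE**: biased correlated random walk — gamma steps (mean 60 m,
  shape 2), wrapped-Cauchy turns (ρ = 0.3), plus a linear drift (0.15 per
  hour) toward the home-range centre, giving a stationary range of a few
  tens of hectares.
- **RELOCATE**: directed travel to a chosen site (gamma mean 200 m,
  truncated at the remaining distance); heading is the circular weighted
  mean (weight 0.7 on the target bearing) of the previous heading and
  the bearing to the target; arrival within 50 m starts attendance.

While foraging, a visit is initiated with per-hour probability
0.7 · p/(4(1−p)) (so time attending ≈ 0.7 p at stationarity), further
gated by min(1, W/0.25) where W is the total site-choice weight
Σ familiarity · exp(−d/400 m) · availability (familiarity 1 for M, 0.1
for A). The gate makes closure divert only part of the thwarted
attendance to alternates — matching the partial compensation seen in the
field — with the remainder spilling into matrix foraging. Closure sets
M's availability to `closure_effect` (0 by default; 1 disables the
manipulation). The home-range centre sits 250 m from M in a random
direction; alternates are placed at N(700 m, 300 m) distances (truncated
at a 100 m minimum spacing) from M. The landscape is a featureless plane:
with ad libitum provisioning at the sites, vegetation depletion plays no
role in the system emulated, so matrix quality is homogeneous.

The population defaults (25 animal-years over three winters, ~28% repeat
individuals, 68% females, Beta(1.7, 3.3) preference with mean 0.34,
exactly 14-day phases at hourly fixes = 1008 slots, optional uniform fix
dropout) mirror the emulated design. Movement constants were chosen by a
coarse grid search (`scripts/calibrate_simulator.py`) against the target
regime — mean hourly displacement ≈ 60 m, mean h_FS ≈ 0.34, pre-closure
home ranges of ~25 ha, pre-closure M-use ≈ 0.3 — and then frozen. All
randomness derives from one integer seed through per-animal-year spawned
streams; identical configurations give byte-identical output bundles.

**What passing on synthetic data shows — and not.** The end-to-end tests
establish that the pipeline recovers known preference (Spearman ≥ 0.8),
reproduces every closure-response direction, and that the mixed-model
machinery is statistically calibrated (coverage, type-I rate). They do
not validate the mover as a model of real herbivore movement: real
trajectories have GPS error, habitat structure, weather- and
diel-dependent activity, and social effects the simulator omits. Absolute
magnitudes (areas, VI levels) on synthetic data are therefore
calibration targets, not predictions.

## Problem sizes and runtimes

Default analyses run a 25-animal-year experiment (~25 000 fixes); the
heavier Monte-Carlo checks use 20 replicates per preference level, 200
replicates for coverage and type-I calibration, and 300 neighbourhoods
for landscape geometry — sizes at which Monte-Carlo error is far below
the tested tolerances while a full test run stays in the low minutes.

## Known limitations

- The binomial GLMM supports a single scalar random intercept (the only
  structure the protocol needs); no random slopes or crossed effects.
- Isopleth areas count grid cells; they converge to contour areas only
  as the resolution refines (the 10 m default is well inside 2%
  stability for bandwidths ≥ ~30 m).
- The lag covariates for the resource models are row-shifts within an
  animal-year's state series; across the (rare) truncation gap between
  phases a lag can reach into the previous phase's last hours.
- No reprojection: coordinates must already be in a metric projected CRS.
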