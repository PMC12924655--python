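# Methods

This note documents the models implemented in `probisim`, the defaults they
ship with, the numerical choices behind them, and what the synthetic data
generator does and does not emulate.

## Generalized Lotka–Volterra community model

Two guilds — probiotics (indexed *i, j*) and pathogens (indexed *k, m*) —
interact through four coefficient families:

```
dP_i/dt = r_i P_i (1 − Σ_j α_ij P_j / K_i) − Σ_k β_ik P_i (P_k / N_ref)
dP_k/dt = r_k P_k (1 − Σ_m γ_km P_m / K_k) − Σ_i δ_ki P_k (P_i / N_ref)
```

Assumptions: well-mixed populations, time-invariant coefficients, no spatial
structure (that is the ABM's job), no stochasticity. Admissible ranges are
r ∈ [0.05, 1.5] h⁻¹, α, γ ∈ [−1, 1] (dimensionless), β, δ ∈ [0, 2]; a
strict-ranges flag controls whether violations raise or only warn.

**Unit diagonal on α and γ.** The intra-guild sums include the self term, so
fixing the diagonals at 1 makes each strain's baseline dynamic exactly
logistic; off-diagonal entries express additional competition or
facilitation between distinct strains of the same guild.

**Reference-density normalization (N_ref).** Cross-guild antagonism terms
are bilinear in abundances; with abundances measured in raw CFU
(10⁸–10⁹/unit) a coefficient scale of [0, 2] would be dimensionally
meaningless (a δ of even 10⁻⁶ would annihilate a population within
seconds). The package therefore applies β and δ to densities normalized by
a reference density N_ref, so the coefficients carry units of h⁻¹ per
N_ref of partner density. N_ref defaults to 10⁸ CFU/unit — the scale of
both the pathogen challenge inoculum (1.5×10⁸ CFU/mL) and the surface
carrying capacity (10⁸ CFU/cm²). This puts the conventional coefficient
ranges, the calibrated δ of the default fixture (≈ 0.27), and
literature-style fitted values (≈ 0.6) on one coherent scale. N_ref is a
model constant, configurable per model.

**Units.** The mode (`liquid` / `surface`) selects K's units (CFU/mL vs
CFU/cm²) and the default integration horizon (48 h vs 21 days); no
conversion between the two unit systems is attempted.

**Integration.** `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
rtol 1e-8, atol 1e-3 CFU, both configurable. The right-hand side clamps
negative states to zero, and output abundances below 1e-6 CFU are clamped
to zero so that numerical dust cannot re-seed an extinct population.

**Time-to-extinction.** For each pathogen, the earliest time its abundance
falls below the threshold and never returns above it within the horizon,
with linear interpolation between output points. The extinction threshold
defaults to 1 CFU per unit — "one viable cell left" — because no numerical
definition of extinction exists for these systems; it is configurable.

**Default single-strain fixture.** r = 0.8 h⁻¹ (probiotic), 0.6 h⁻¹
(pathogen), K = 10⁹ CFU/mL, β = 0.05, inocula 5×10⁹ (probiotic) and
1.5×10⁸ CFU/mL (pathogen) — the standardized suspension densities used for
probiotic and indicator-pathogen preparations. δ is not fixed a priori: it
is calibrated by bisection so the pathogen extinction time hits a chosen
target (±0.05 h). Extinction time is strictly decreasing in δ, so plain
bisection on [0, 2] converges; an unattainable target is reported with the
bracketing values.

**Consortium experiment.** The baseline probiotic is replicated n times
with identical parameters, each copy seeded at the same per-strain inoculum
(total probiotic load scales with n, mirroring an equal-ratio multi-strain
blend). The probiotic–probiotic α matrix is the identity: strains are
modeled as mutually non-competing because the delivery system
compartmentalizes them in separate carrier beads. Per-strain δ values
default to the calibrated baseline δ replicated; a custom per-strain table
can be supplied. The experiment reports baseline and consortium extinction
times and their ratio.

## Coefficient inference

* **Loss.** Residuals on log₁₀(abundance + 1) between simulated and
  observed series, summed over non-missing cells. The log transform
  stabilizes the ~8 orders of magnitude a kill curve spans; the +1 keeps
  zeros finite. Missing observations are dropped, never imputed.
* **Initial condition.** The dataset's first observed row (it must be
  complete).
* **Optimization.** `scipy.optimize.least_squares` (trf) within bounds,
  with 8 starts drawn uniformly in bounds from a seeded generator (gLV
  least squares is multi-modal); tight stopping tolerances (1e-12) so that
  noise-free data is recovered to numerical precision. The best converged
  start wins; total failure is an explicit error.
* **Bootstrap.** Residual resampling within each strain's series on the
  log scale (the dataset's own first row stays the initial condition),
  refitting from the point estimate; 1,000 resamples by default, seeded and
  bit-reproducible. Percentile 2.5/97.5 intervals and the SD across
  resamples are reported; more than 10% failed resamples is an error. A
  case-resampling scheme (whole time points) is available behind a flag.
* **Recovery studies.** `recovery_study` generates replicate synthetic
  datasets from a known truth, refits each, and tabulates bias, RMSE and
  median absolute error per coefficient — the package's own check that the
  estimator recovers what the generator planted.

## Spatial agent-based model

A discrete-time stochastic simulation on a rectangular patch grid. The
defaults model a 1 cm² arena: 100×100 patches of 0.01 cm, 500 timesteps of
172.8 s (= 24 h). Four guilds: A secretes M1 (lipopeptide-like), B secretes
M2 (organic acid), C is oxygen-sensitive and cross-fed by M2, P is the
pathogen. The per-step stage order is fixed and documented (growth,
secretion, diffusion+decay, cross-feeding, antagonism, biofilm flagging,
starvation), as is the order in which random draws are consumed, so a run
is a pure function of (config, params, seed).

Key rules and defaults:

* **Growth**: each agent divides with probability r × (dt in h) × local
  nutrient × O₂ response × hydration, capped at 1. r defaults: A 0.6,
  B 0.7, C 0.5, P 0.6 h⁻¹. The O₂ response is O₂/O₂_max for A, B, P and
  (1 − O₂/O₂_max) for C (oxygen-sensitive metabolism). Hydration is a
  scalar 0.6 — the midpoint of the 0.5–0.7 water-activity range a carrier
  film maintains. Daughters stay in the parent patch below the crowding cap
  (30 agents), else move to a random neighbor; a full neighborhood drops
  the division.
* **Nutrient / O₂**: uniform initial pools, consumed per division
  (0.005 each), no nutrient replenishment by default (surface scenario;
  inflow configurable). O₂ diffuses and is replenished by relaxation along
  the boundary, which creates the interior hypoxia Type C benefits from.
* **Secretion / diffusion**: A and B deposit 1.0 field unit per agent per
  step into their patch. Fields diffuse with D = 10⁻⁶ cm²/s (admissible
  10⁻⁷–10⁻⁵) by an explicit 5-point stencil with no-flux boundaries,
  substepped so each substep satisfies D·dt/h² ≤ 0.25 (7 substeps at
  defaults); diffusion conserves mass to floating precision. Fields decay
  1% per step.
* **Cross-feeding**: Type C gets an extra division opportunity scaled by a
  Hill response of local M2 (n = 2, half-saturation 40 ≈ 10% of the
  quasi-steady M2 mean under default secretion, calibrated once and
  frozen).
* **Antagonism**: a pathogen whose local M1 *or* M2 exceeds its threshold
  (θ = 160 for both) dies with probability p_k = 0.2 that step. The
  "M1/M2 > threshold" condition is read with the slash as "or"; a ratio
  interpretation (M1/M2 as a quotient) is available behind a flag and logs
  a warning.
* **Biofilm**: a patch reaching 20 agents is flagged (sticky). Flagged
  patches exempt their occupants from starvation death — the one
  consequence attached to the transition here; the underlying biology
  (matrix protection) suggests several, and this is the most conservative.
* **Starvation**: agents on nutrient-exhausted patches lose one energy
  unit per step (initial reserve 10) and die at zero unless on biofilm.

Grid size, initial densities (A 300, B 500, C 400, P 200, uniformly
placed), the nutrient/O₂ sub-models, secretion rates, thresholds and Hill
constants are declared package defaults — no standard values exist for
them. They were set so that the default scenario reproduces the headline
spatial outcome (pathogen exclusion in 100% of replicates within 300–400
steps); everything else (halo formation, biofilm dominance, cross-feeding
niches) is emergent, reported but not calibrated.

Outputs per replicate: population time series, first pathogen-free step
(exclusion step), end-state dominance heatmap (winning type per patch, ties
broken A > B > C > P, exported as integer CSV), and the Type-A peripheral
enrichment ratio (share of A in the outer annulus over its share in the
interior; > 1 = halo-like edge colonization). `sensitivity_scan` runs a
full-factorial sweep over any parameter subset with per-cell seeded
replicates.

## Efficacy statistics

* Plate enumeration keeps colony counts in the closed [30, 100] window,
  averages replicates at a dilution, computes density = mean count /
  plated volume × dilution factor (default 0.05 mL aliquots), and averages
  log₁₀ densities across countable dilution levels. No countable plate ⇒
  an explicit "uncountable" result, never an extrapolation.
* LR = control − treated (log₁₀ scale, may be negative);
  PR = (1 − 10^−LR) × 100 exactly, rounded only at the reporting layer.
  The bundled reference efficacy values include one PR cell (LR 1.98,
  reported as 98.94%) that disagrees with this formula at 2 d.p.
  (formula: 98.95%); the package documents rather than resolves the
  discrepancy and excludes that cell from exact checks.
* Group comparisons use the pooled-variance two-tailed Student's t
  (Welch behind a flag), significance at p < 0.05, no multiple-testing
  correction (per-comparison tests only, deliberately mirroring common
  reporting practice in this literature).
* Zone summaries use the sample (n−1) SD — consistent with the bundled
  43-strain reference table's summary (13.84 ± 1.23 mm).
  Bactericidal fraction = percent of strains with a Negative subculture.
* Formulation arithmetic: slurry CFU/mL = load × mass / volume; a 1:1
  blend with sterile carrier halves the concentration.

## Synthetic-data generator

Every generator is a pure function of (parameters, seed), and zero-noise
output lies exactly on the declared mean structure.

* **Coculture**: gLV simulation plus an observation model — none,
  multiplicative lognormal (observed = truth × exp N(0, σ)), or a full
  plate-count pipeline (Poisson colony draws at auto-bracketed ten-fold
  dilutions, re-enumerated through the countable-window estimator;
  uncountable cells become missing values). Generating coefficients are
  recorded as metadata for recovery studies.
* **Plate counts**: Poisson with mean density × volume / dilution (pure
  counting noise; no overdispersion by default).
* **Storage viability**: per-temperature log₁₀ CFU/mL curves from an
  initial level of 7.9. Frozen (−20 °C) and refrigerated (4 °C) profiles
  decline log-linearly to total day-365 losses of 0.46 and 0.89; the
  ambient (24 °C) profile is biphasic — linear rise of 0.3 to a day-7 peak,
  plateau to day 10, then linear decline to a total day-365 loss of 4.51.
  Between anchors the curves interpolate piecewise-linearly in log space
  (only anchor values are specified). Gaussian observation noise
  (SD 0.05 by default) sits on top; the replicate-batch variance structure
  of real storage series is unknown, so this SD is a declared fixture
  value, not an estimate.
* **Surface survival**: piecewise-linear log₁₀ CFU/cm² through the anchors
  7.07 (day 0), 7.18 (day 1), 6.65 (day 7), 6.05 (day 14), 5.48 (day 30):
  a 24 h colonization rise, then a monotone decline that stays above the
  5-log protective floor.
* **Zone tables**: integer-rounded Gaussian diameters and Bernoulli
  bactericidal outcomes; plus the bundled literal 43-strain reference table
  so exact-summary tests need no re-transcription.

What the generator does *not* emulate: mechanistic thermal-inactivation
kinetics, strain-resolved storage dynamics, plate-count overdispersion
(available but off by default), matrix effects on recovery, and any
correlation structure between replicates. Passing tests therefore
demonstrate that the pipeline's arithmetic and inference are correct under
the stated noise models — not that those noise models capture every feature
of real laboratory data.

## Problem sizes and runtime choices

The shipped test suite and the acceptance script run the gLV experiments at
full scale (48 h horizons, 0.02 h output grids) and the ABM at its default
scale (100×100 × 500 steps × 10 replicates). Statistical studies use
moderate replicate counts chosen for tight-enough Monte-Carlo error: 20
replicates for the noisy-recovery study, 200 seeds for the plate-count bias
study, 20–40 bootstrap resamples in tests (the production default is
1,000). Bootstrap-CI *coverage* is not re-estimated in the test suite — a
calibrated coverage study needs hundreds of dataset × bootstrap
combinations; the suite instead verifies the bootstrap's degenerate
(noise-free), bracketing and reproducibility properties.

## Known limitations

* The gLV coefficient scale depends on the declared N_ref normalization;
  coefficients are comparable across studies only relative to it.
* The ABM's nutrient, O₂ and secretion sub-models are minimal declared
  constructions; quantities like θ and secretion rates are in arbitrary
  field units, so only their ratios are meaningful.
* Bisection calibration assumes extinction time is monotone in δ, which
  holds for this model family but is not checked globally.
* The fitting module estimates coefficients of the same model family that
  generated the data; structural misspecification is out of scope.
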