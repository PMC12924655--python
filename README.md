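# probisim

Ecological modeling and efficacy statistics for probiotic-based surface
disinfection. The package simulates how a consortium of probiotic strains
suppresses and excludes pathogens — in bulk culture through a generalized
Lotka–Volterra (gLV) community model, and on surfaces through a spatially
explicit stochastic agent-based model (ABM) with metabolite secretion,
diffusion, cross-feeding and antagonism — and provides the disinfection-trial
statistics (CFU enumeration, log/percent reduction, inhibition-zone and
bactericidal summaries) used to report such experiments. A synthetic-data
generator emulates every laboratory input (coculture time series, plate
counts, storage-viability and surface-survival curves, zone tables), so the
whole pipeline is testable without any external data.

It is aimed at microbiologists and modelers evaluating probiotic
disinfectants based on competitive exclusion (Gause's principle).

## Models

**gLV community model.** With probiotics indexed *i, j* and pathogens *k, m*:

```
dP_i/dt = r_i P_i (1 − Σ_j α_ij P_j / K_i) − Σ_k β_ik P_i (P_k / N_ref)
dP_k/dt = r_k P_k (1 − Σ_m γ_km P_m / K_k) − Σ_i δ_ki P_k (P_i / N_ref)
```

`r` are growth rates (0.05–1.5 h⁻¹), `K` carrying capacities (10⁹ CFU/mL
liquid, 10⁸ CFU/cm² surface), `α, γ ∈ [−1, 1]` intra-guild competition with a
unit diagonal (logistic self-limitation), and `β, δ ∈ [0, 2]` the cross-guild
antagonism coefficients acting on densities normalized by a reference density
`N_ref = 10⁸` CFU/unit. The module integrates the system with a
stiff-capable adaptive solver, extracts per-pathogen time-to-extinction
(threshold 1 CFU/unit, linearly interpolated), calibrates the single-strain
fixture by bisection on δ, and compares single-strain versus consortium
suppression. Interaction coefficients can be inferred from (noisy) coculture
time series by bounded multi-start nonlinear least squares on
log₁₀(abundance + 1), with residual-resampling bootstrap uncertainty
(n = 1,000 by default).

**Spatial ABM.** Four agent guilds on a 100×100-patch, 1 cm² arena: Type A
(*Bacillus*-like) secretes the antimicrobial field M1, Type B
(*Lactobacillus*-like) secretes the organic-acid field M2, Type C
(*Bifidobacterium*-like) is oxygen-sensitive and cross-fed by M2 through a
Hill response, and Type P pathogens die with probability p_k = 0.2 per
timestep wherever M1 or M2 exceeds its threshold. Metabolites diffuse by an
explicit, mass-conserving 5-point stencil (D = 10⁻⁶ cm²/s, substepped for
stability); patches reaching 20 agents convert to biofilm. 500 timesteps of
172.8 s ≈ 24 h.

**Efficacy statistics.** Plate counts in the countable 30–100 colony window
are converted to log₁₀ CFU/mL; log reduction LR = control − treated;
PR = (1 − 10^−LR) × 100; pooled-variance two-tailed Student's t-tests;
inhibition-zone mean ± sample SD and the bactericidal (no-regrowth) fraction.

## Worked example

```python
from probisim import glv

# Calibrate the single-probiotic fixture so the pathogen (inoculated at
# 1.5e8 CFU/mL against 5e9 CFU/mL probiotic) goes extinct at 6.5 h...
base = glv.calibrate_single_strain(6.5)
print(f"delta = {base.delta:.4f}, extinction at {base.extinction_time:.2f} h")

# ...then expand to a 12-strain consortium at the same per-strain inoculum.
rep = glv.consortium_experiment(base.model, n_strains=12)
print(f"consortium extinction at {rep.consortium_time:.2f} h")
```

prints

```
delta = 0.2676, extinction at 6.49 h
consortium extinction at 0.14 h
```

i.e. multi-strain synergy collapses the time-to-extinction from 6.5 h to
well under 1 h. The same experiments are available from the shell:

```
$ probisim glv consortium
baseline 6.49 h -> consortium 0.14 h (n=12)

$ probisim stats zones
inhibition zones: 13.84 ± 1.23 (n = 43); bactericidal 34.9%

$ probisim abm run --replicates 10
exclusion probability 100%; steps [315, 302, 332, 320, 304, 305, 310, 332, 312, 327]
```

The last command runs the default spatial scenario: pathogens are excluded
in every replicate within 300–350 of the 500 simulated steps.

## Layout

- `src/probisim/glv.py` — gLV model, integration, extinction, calibration,
  consortium experiment
- `src/probisim/fit.py` — coefficient inference, bootstrap, recovery studies
- `src/probisim/abm.py` — spatial agent-based model and summaries
- `src/probisim/efficacy.py` — disinfection-trial arithmetic and statistics
- `src/probisim/synth.py` — synthetic-data generators and the bundled
  reference zone table
- `src/probisim/cli.py` — `probisim` command-line interface
- `docs/methods.md` — modeling assumptions, parameter defaults, numerical
  choices and limitations
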