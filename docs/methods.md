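# Methods

`idepsep` models scanning-voltage direct-current insulator-based
dielectrophoresis (DC-iDEP) separation of sub-micron bioparticles — the
workflow used to resolve organelle subpopulations such as insulin secretory
vesicles — from channel electrostatics through particle trapping to the
between-condition statistical comparison. This note records the model, its
assumptions, the default parameters and why they were chosen, and what the
synthetic data do and do not establish.

## Physical model

**Transport.** A particle in a DC field moves electrokinetically with
velocity `v_EK = μEK·E`, where `μEK = μEP + μEOF` combines electrophoresis
and electroosmosis, and dielectrophoretically with `v_DEP = μDEP·∇|E|²`,
where

    μDEP = εm r² fCM / (3η)

with particle radius `r`, Clausius–Mossotti factor `fCM`, and medium
permittivity `εm` and viscosity `η`. Trapping at a constriction requires the
DEP term to oppose electrokinetic motion; balancing the two velocity
magnitudes gives the capture condition

    (∇|E|² · E) / |E|²  ≥  μEK / μDEP  ≡  EKMr   [V/m²].

The left side (the *capture parameter* `c`) is a property of the device and
applied voltage; the right side (the electrokinetic-to-dielectrophoretic
mobility ratio) is a property of the particle. We report EKMr as a positive
magnitude, as is conventional; in the trajectory integrator, where signs
matter, a trapping particle carries signed `μDEP < 0`.

**Device.** The reference channel is 3.5 cm long and nominally 20 μm deep
(depth is metadata; the field model is 2-D), with 27 gates formed by paired
triangular teeth. Gate openings step from 73 μm down to 25 μm in nine
groups of three equal-width gates. The printed endpoints fix an exact
linear schedule (6 μm steps); the schedule is overridable. Tooth apex
half-angle (30°), background channel width (200 μm) and gate pitch
(length/28, so 27 gates fit with margins) are not dictated by the fabricated
device's published description; they affect the absolute capture-parameter
scale, which is handled by calibration (below), not the model's logic.

**Field solution.** Laplace's equation is discretized with 5-point finite
differences on a cell-centered raster of the fluid region (Dirichlet inlet
and outlet faces via ghost cells; zero-flux ghosts on insulating
boundaries) and solved by sparse LU; the relative residual is checked
against 1e-8. `E` comes from central differences (one-sided at walls);
`∇|E|²` is differenced from the `|E|²` grid rather than by second
differentiation of `E` components, to avoid compounding stencil error. In a
straight channel this machinery reproduces `|E| = V/L` to ~1e-9 relative
and `c ≡ 0`; by linearity of the Laplace problem, all fields scale with the
applied voltage and `c` scales linearly, so per-gate thresholds are stored
at 1 V applied and multiplied by voltage on demand.

**Gate thresholds.** The threshold of a gate is the largest capture
parameter a particle traversing the gate must overcome. We evaluate `c`
along the channel centerline — the path a centered particle actually
samples — over an axial window covering the gate's approach (the tooth
footprint plus the constriction depth, plus a 5-cell margin) and take the
maximum of its positive part. Two numerical points motivated this
definition. First, `c` peaks 10–15 cells *upstream* of the throat, where the
field magnitude is still rising; a window confined to the throat
underestimates the path maximum and makes the threshold predictor disagree
with integrated trajectories. Second, a maximum taken across the whole
throat cross-section is dominated by the discretization singularity at the
tooth tips, which a centerline particle never encounters and which does not
converge under grid refinement. With the centerline definition, halving the
grid spacing moves toy-gate thresholds by ≈3.5% (first-order convergence,
dominated by the reentrant corners' influence on the near-throat field).

Gate axial positions are snapped to the nearest cell center during
rasterization (a ≤ h/2 geometric perturbation). Without snapping, the gate
pitch aliases against the grid with a period that coincides with the width
groups, producing spurious ~4% threshold differences between nominally
identical gates; with it, equal-width gates have bitwise-identical local
rasters and thresholds, and the thresholds increase strictly from one width
group to the next.

**Calibration.** The absolute scale of `c` depends on tooth-shape
parameters that are configuration, not measurement. `gate_thresholds`
therefore carries a multiplicative calibration factor (default 1.0), and
the packaged experiment pipeline pins the last gate's threshold at 1800 V
to 2.3×10¹⁰ V/m² — the largest EKMr at which signal was observed in the
reference experiment (calibration factor ≈ 1.63). Uncalibrated, the scan
(600–1800 V) spans thresholds of 5.0×10⁸–1.4×10¹⁰ V/m²; calibrated,
8.1×10⁸–2.3×10¹⁰ V/m².

**Scanning protocol.** Default: block at 2100 V (every particle's EKMr is
below the first gate's threshold, so nothing enters), then read out at
1800, 1500, 1200, 900, 600 V. At each step a particle advances from its
current gate to the first gate at or downstream whose threshold
`V·c_g ≥ EKMr` (equality captures, compared at 1e-12 relative tolerance),
or exits. Particles are independent; each voltage is an equilibrium
snapshot (the experimental 90 s settling time is not simulated). Capture
state moves only downstream as voltage drops. Raw per-gate intensity is the
summed fluorescence weight of trapped particles, optionally plus a flat
imaging background and seeded Gaussian readout noise.

## Trajectory oracle

The capture predictor is checked against an independent Euler–Maruyama
integrator of `dx/dt = μEK·E + μDEP·∇|E|²` (+ optional Brownian term) with
bilinear field interpolation, reflecting walls, and adaptive time-stepping
capped at half a grid cell per step. Capture is declared when mean
displacement over a trailing 500-step window falls below 0.01 cells; exit
when the particle passes the last cell center. On a three-gate toy channel,
deterministic trajectories land at the predicted gate for every test EKMr
more than 5% away from a threshold (near-threshold ties excluded), and the
classification is stable under time-step halving. When diffusion is
enabled, Stokes–Einstein from `r` and `η` is the physically sensible
coefficient; defaults keep it off because the capture model being checked
is deterministic.

## Synthetic populations and the simulated experiment

Subpopulations are specified directly in EKMr space — the observable the
separation indexes on — as log-normal mixture components (positive support,
right skew; dispersion is the log-space SD). Physical parameters are
back-filled consistently: radius 175 nm (mid-range of the 150–200 nm
vesicle radii), `fCM = 0.5`, medium `εm = 78 ε₀`, `η = 1.2e-3 Pa·s`
(sucrose-based low-conductivity buffer), `μEOF = 0` (BSA-passivated
channel), and `μEK = EKMr × μDEP`. The round trip through `dep_mobility`
and `ekmr` reproduces each drawn EKMr to 1e-12 relative.

The packaged two-condition presets anchor component locations to the EKMr
features reported for untreated ("n": 3.5, 5.5, 12, 18 ×10⁹ V/m²) and
glucose-stimulated ("g": 4, 7.5, 11, 23 ×10⁹ V/m²) vesicles. Component
weights (equal), dispersions (0.18) and brightnesses (equal) are
illustrative — the experiment does not quantify them. The simulated
experiment uses 3 replicates for "n" and 4 for "g", 20 000 particles per
replicate, 2% readout noise and a 5% flat background (fractions of the mean
per-gate signal), and replicate-level biological variability: each
replicate's mixture weights are Dirichlet-jittered (concentration 50) and
its component locations log-normally jittered (5%). Without
replicate-level variability, between-replicate variance is implausibly
small and interaction F statistics are inflated a hundredfold.

What the synthetic data do *not* emulate: bolus growth dynamics and
particle–particle crowding, gate-to-gate optical variation, photobleaching,
condition-dependent labeling efficiency, or any physical linkage between a
vesicle's EKMr and its brightness. Passing tests therefore establish the
internal consistency of the pipeline (field → thresholds → capture →
spectra → inference), not the biological fidelity of any particular
spectrum.

## Spectra

Processing mirrors the measurement pipeline: background subtraction
(clamped at zero), normalization within each (condition, replicate,
voltage) group, aggregation of each width-triplet of gates (intensity =
mean over the three gates; EKMr coordinate = voltage × mean unit threshold
of the group), then replicate mean ± SEM. Normalizing per replicate before
averaging keeps replicates on a common scale. The normalization denominator
is the group maximum by default; a `sum` mode is provided because the
reference description is ambiguous between the two. All-zero groups pass
through with a warning; single replicates report SEM as NaN.

## Statistical comparison

Per-replicate triplet intensities at one readout voltage enter a two-way
fixed-effects ANOVA, condition × EKMr level with interaction, fitted by
OLS with sum-to-zero contrasts (statsmodels). In the reference design
(2 × 9 levels, 3 + 4 replicates) the interaction has 8 df against 45 error
df. The interaction F is invariant to the sum-of-squares type; main
effects, which are type-dependent under imbalance, are reported from the
Type III table. Designs with empty cells are rejected; a design with zero
residual variance reports SS with undefined F. Post hoc, each level gets a
two-sample comparison of condition means using the pooled error mean
square (error df from the full model), with raw p values multiplied by the
number of levels and capped at 1; the significance flag uses α = 0.05 to
match the reference analysis, configurable. Under a null simulation (both
conditions sharing level means; 1000 simulated experiments) the interaction
test rejects at the nominal 5% within binomial error.

## Numerical choices and degenerate inputs

- Raster spacing must give the narrowest gate ≥ 8 cells; reference-device
  work uses 3 μm (the coarsest admissible spacing; one solve ≈ 15 s on one
  core), toys 1–2 μm.
- |E| floor for evaluating `c`: 1e-6 × median fluid |E| (cells below it are
  flagged NaN, not divided).
- Capture tie-break: equality captures, at 1e-12 relative tolerance.
- Disconnected rasters are rejected; enclosed insulator pockets at coarse
  rasters are dropped to the main component.
- Seeds: every stochastic element (population draws, replicate jitter,
  readout noise, Brownian term) is derived from explicit integer seeds;
  labels enter substreams through CRC32, never Python's salted `hash`.

## Known limitations

- 2-D electrostatics: real devices have finite depth and top/bottom walls;
  absolute thresholds are calibrated, not predicted.
- First-order threshold convergence near reentrant tooth corners.
- The capture rule treats particles independently and as points; no
  volume exclusion at a full gate, no overtaking effects.
- EKMr is treated as scalar and voltage-independent (linear DC theory);
  field-dependent polarization is outside the model.
- The ingestion path for externally recorded intensity tables requires the
  published source file, which ships separately from this package.
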