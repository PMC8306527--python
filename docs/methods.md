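# Methods

## Overview

`asyncgc` simulates the population of germinal centers (GCs) that forms in a
lymphoid organ after a primary immunization. Individual GCs are stochastic
agent-based simulations of B-cell expansion, somatic hypermutation, antigen
collection from follicular dendritic cells (FDCs) and selection by T
follicular helper (Tfh) cells. A cohort layer schedules a small number of
*representative* GCs along a Hill-function formation curve and weights them
up to organ scale, producing the two observables that published kinetics
report: the number of active GCs over time and the total GC volume. A fitting
layer scores simulated kinetics against experimental-style series with a
relative squared-error cost, and a synthetic-data generator provides targets
with known ground truth so the full pipeline is testable end to end.

## Single-GC model

Cells and processes follow the agent-based GC modeling tradition, reduced
from a spatial lattice to well-mixed dark-zone/light-zone compartments:

- **Founder influx.** Seeder B cells arrive as a Poisson process at 2
  cells/h for the first 96 h and undergo 6 initial divisions before acquiring
  a light-zone phenotype.
- **Shape space.** Affinity is encoded on a 4-D integer lattice (axes 0..9
  by default): a B cell's affinity for an epitope is exp(−d²/Γ²) in the
  distance d to the epitope's optimal position. Somatic hypermutation moves
  one coordinate by ±1 with probability 0.5 per division. Multiple unrelated
  epitopes are optima placed far apart with antigen shares given by their
  abundance fractions; the multi-epitope scenarios enlarge the lattice to
  0..15 so the optima sit ≥ 21 units apart and cross-reactivity under the
  calibrated kernel width is negligible (< 1e-5) — which is what
  "unrelated" has to mean once Γ is wide.
- **Antigen collection.** Each FDC carries 3000 antigen portions initially
  (600,000 for 200 FDCs), split across epitopes by abundance. An unselected
  LZ cell has a 0.7 h collection window with one binding attempt per 0.1 h
  timestep; the engaged epitope is drawn proportional to remaining portions
  weighted by the cell's affinity for each epitope (cognate capture — a BCR
  does not extract antigen it cannot bind) and an attempt succeeds with probability affinity × (1 −
  feedback_strength × masked fraction), transferring one portion. Cells that
  end the window empty-handed die.
- **Antigen decay and FDC release capacity.** FDC-held antigen decays at
  rate `fdc_decay_rate` (0.0046/h by default; degradation and consumption by
  non-GC processes, tracked as its own conservation bucket with integer
  per-step binomial draws), and FDCs release to B cells at most
  `fdc_release_rate` × remaining portions per hour (0.0001/h; the finite
  antigen-presenting surface), with excess successful binders in a timestep
  rationed at random. The antigen stock is therefore an exponential clock
  whose rate is independent of selection stringency, and the sustainable
  B-cell population is slaved to the remaining stock. GC contraction is
  gradual, its duration grows logarithmically with the initial loading
  (~8.7 days per e-fold), so heavily loaded GCs are long-lived, and changes
  to selection stringency shift the population level — and hence the time
  of crossing the 100-cell counting threshold — without touching the
  antigen clock. The steady-state GC in this economy is small (a few
  hundred to a few thousand cells after the founder-expansion wave);
  absolute cell numbers are not calibrated to histology — only the
  threshold-crossing kinetics and the volume curve up to normalization are
  interpreted.
- **Tfh-mediated selection.** A cell that collected antigen enters a 36-min
  contact with a uniformly chosen Tfh. In each timestep the Tfh polarizes to
  the *adjacent* contender holding the most antigen (ties uniformly at
  random); each contacting cell is adjacent with probability
  `tfh_adjacency_prob` per step, the well-mixed abstraction of B/Tfh
  motility during a contact. A cell is selected if it accrues at least
  30 min of polarized help by the end of its contact, and dies otherwise.
- **Division and output.** A selected cell divides min(1 + ⌊log₂(1 +
  antigen)⌋, max_divisions) times; 72% of divisions are asymmetric, passing
  all antigen to one daughter. Terminal daughters retaining at least one
  full portion leave as plasma cells; the remainder re-enter collection with
  probability 0.8 (recycling) and are lost otherwise, their residual antigen
  cleared.
- **Antibody feedback** (optional): plasma output accumulates an
  affinity-weighted count P_w per epitope; a masked fraction P_w/(P_w + K)
  lowers collection success multiplicatively with strength `feedback_strength`.

All per-cell clocks are integer timestep counts and antigen amounts are
dyadic rationals, so the conservation audit

    initial portions = remaining + held by live cells + carried by output
                       + lost with dead/recycled cells + decayed

holds exactly in floating point at every recorded step.

## Cohort layer

Cumulative GC formation follows N(t) = Nmax·tⁿ/(Tⁿ+tⁿ). The formation window
is split into equal intervals (8 by default; 15 for extended formation); one
representative GC is simulated per interval with weight N(end) − N(start),
and its initiation time is drawn from a Gaussian centred on the interval
midpoint (width 24 h, truncated to the interval). Every represented GC
shares its representative's trace and initiation time. A GC counts as active
while its live-cell count exceeds 100; its lifetime is the total time spent
above that threshold. Total volume uses the live-cell count as a volume
proxy and is normalized to day 7 whenever compared with data.

## Hypothesis scenarios

| id | variation | per-GC effect |
|----|-----------|----------------|
| H1 | none (baseline) | identical parameters, formation ≤ 12 d |
| H2 | extended formation | identical parameters, 15 intervals to day 35 |
| H3 | antigen decay | loading A₀e^(−k·t_init) per FDC (Rao fit: A₀=20,000, k=0.026/h) |
| H4 | founder specificity | 3 epitopes at 0.6/0.3/0.1; early/late intervals get random vs epitope-specific founders |
| H5 | random loading | loading ~ N(3000, 1500) truncated at 100, independent of t_init |
| H6 | antibody feedback | feedback_strength > 0, single or multiple epitopes |
| H7 | founder influx | per-GC influx-rate multipliers |
| H8 | founder affinity | per-GC founder distance from the optimum |

H2 carries its own reference antigen loading (2250 portions/FDC): the
extended-formation fit in the literature used a separately tuned parameter
set, and with literally identical parameters H1 and H2 lifetimes would be
identically distributed. The H5 antigen draws are re-sampled on every
simulation repeat, so a single repeat shows large within-cohort lifetime
variability while repeat-averaged per-representative lifetimes are flat in
initiation time.

## Cost and model selection

The model-to-data cost is Σᵢ((Eᵢ−Sᵢ)/Eᵢ)² over matched time points, computed
on the across-repeat mean curve; GC-count and volume costs are added with
equal weight, with volume normalized at day 7 on both sides. The central
qualitative result is an ordering, not a cost value: against a target with a
prolonged contraction phase, the baseline 12-day-formation scenario scores
worse than the variable-lifetime scenarios.

## Synthetic targets

The published series are digitized histology figures and are not deposited,
so synthetic targets emulate their structure: Hill-law formation (default
target Hill coefficient 1.5, which puts measurable formation mass into the
first day as the emulated data show), per-GC lifetimes either fixed or
mapped from decaying antigen (L = 8.8 d × log1p(A/757), mirroring the
simulator's own lifetime-vs-loading response so the decay truth is the
closed-form surrogate of a cohort in which loading falls with initiation
time), triangular per-GC volume kernels peaking at 40% of lifetime, day-7
volume normalization, and multiplicative lognormal noise (sd 0.15).
Sampling days run through day 25 and volume points below a 2% detection
limit are unreported: the relative squared-error cost is undefined at zero
and explodes near it, and histology would not report such values either.
The generator reproduces the qualitative features the analyses rely on —
peak near day 9–12, a contraction phase that is much more prolonged under
antigen decay than under fixed lifetimes — but not histology-specific error
structure; passing tests show pipeline correctness and qualitative
transferability, not quantitative agreement with any specific published
dataset.

Hill parameters are recovered from the rising phase of a count series by
nonlinear least squares (`scipy.optimize.curve_fit`, bounded, initialized
from the half-maximum crossing).

## Calibration of engine defaults

The spatial base model this design descends from fixes its encounter
processes through lattice geometry; the well-mixed reduction replaces them
with rate parameters that have no printed values. These were calibrated
once, jointly, so that the reference parameterization reproduces the
published cohort-level outcomes (baseline mean lifetime ≈ 12.5 d and the
directional lifetime sensitivities), and are not varied per scenario:
`fdc_decay_rate` (0.0046/h), `fdc_release_rate` (0.0001/h),
`tfh_adjacency_prob` (0.72), the affinity width Γ (6.0 at the engine level;
the stand-alone kernel keeps its narrower nominal default), the Tfh count
(1000), and the selection-induced division cap (3, so that the mean number
of divisions per selection round is ~2, the same calibration target the
base-model lineage uses). Division cycle times are gamma-distributed with
mean 7.5 h and CV 0.2.

## Numerical choices

- Timestep 0.1 h; it divides the 36-min contact (6 steps), the 30-min
  polarization threshold (5 steps) and the 0.7 h collection window (7 steps)
  exactly; clocks are integer step counts.
- Time series are recorded every 6 h; lifetimes are computed on that grid
  (each supra-threshold record contributes one recording interval), and the
  run ends early once the GC is extinct and influx has ceased.
- "Above the threshold" is strict (live cells > 100).
- Ties in Tfh polarization are broken uniformly at random per timestep.
- Master seeds spawn per-(representative, repeat) child seeds via numpy
  SeedSequence spawn keys, so adding repeats never changes earlier runs and
  results are independent of execution order.
- Sweeps reuse one seed list across swept values (common random numbers);
  the reference value therefore normalizes to exactly 1.

## Problem sizes

Cohort checks use 8–15 representatives with 10 repeats (50 for the
random-loading scenario's repeat-averaged structure) and sweeps use 10 seeds
per value; these sizes give stochastic-mean standard errors well inside the
tolerances asserted in the tests while keeping the full suite quick to run.

## Known limitations

- No spatial lattice, chemokine fields or migration; encounter processes are
  per-timestep probabilities. DZ/LZ ratios and spatial readouts are out of
  scope.
- No memory-cell output class; output is a single plasma-cell channel.
- Representative weighting assumes every GC in an interval behaves exactly
  like its representative; within-interval variability is not modeled.
- No inter-GC coupling (shared Tfh or antibody exchange between live GCs);
  antibody feedback acts only within a GC.
- The division-number mapping from collected antigen and the affinity kernel
  are plausible forms calibrated to cohort-level outcomes, not measured
  per-cell dose-response curves.
- Antibody feedback has little effect on lifetime in this calibration:
  feedback lowers per-attempt binding success, but under release-limited
  rationing a drop in per-cell success is compensated by less rationing, so
  the population and the antigen clock barely move. Feedback-driven
  lifetime variability would require feedback to act on the release or
  decay pathway instead.
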