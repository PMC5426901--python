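# Methods

This note documents the models implemented in `ubnmr`, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and philosophy

The package models the quantitative workflow of a methyl-TROSY NMR study
of a reader protein binding a ubiquitylated nucleosome core particle
(NCP): equilibrium and kinetic binding analysis from titrations, particle
hydrodynamics from gradient-encoded decays, methyl-axis rigidity from
triple-quantum relaxation, and the restraint machinery of replica-averaged
restrained molecular dynamics. Every fitting stage has a synthetic
counterpart drawing from the identical forward model, so the whole
pipeline closes: with zero noise each fit reproduces its generator to
machine precision, and at realistic noise the recovery error is itself a
measured quantity.

## Units

nm, kJ/mol, ps, amu and K internally for mechanics (so printed force
constants in kJ/(mol nm²) are used verbatim, and k_B = 0.008314 kJ/(mol K));
ppm for chemical shifts, Hz for frequency offsets (conversion always
through an explicit spectrometer frequency in MHz, never inferred), µM for
concentrations, s for relaxation delays, cm²/s for diffusion constants.
All conversions happen at module boundaries.

## Chemical-shift perturbations

CSP_i = sqrt(ΔδH² + ΔδC²·w) with w = σ_H/σ_C per methyl type, from a
bundled BMRB-derived dispersion table (ratios 0.16–0.18; the table is an
argument, so a user can substitute their own σ values). Significance uses
the sample (n−1) standard deviation — the population/sample choice is not
canonical in the field, so it is exposed as `ddof` — and a strict
inequality, which makes the degenerate all-equal case flag nothing.
Leu/Val methyls without stereospecific assignments are paired onto
upfield/downfield "a"/"b" labels by sorted ¹H shift within each residue.

## Binding isotherms

The bound fraction is the exact quadratic root of 1:1 mass action, valid
under ligand depletion (no free ≈ total approximation); a property test
checks it against an independent root-finder to 1e-10 over random grids.
Two fit modes exist: per-residue (K_d, Δδ′_max) fits whose across-residue
mean ± sd is reported — the convention when per-peak isotherms are fitted
individually — and a global shared-K_d fit with per-residue endpoints.
Per-residue is the default. The optimizer is bounded least squares
multi-started from log-spaced K_d values (7 starts over 1e-2–1e5 µM) to
avoid local minima in the weak-binding regime. An optional fast-exchange
filter drops residues whose full shift change exceeds a Hz threshold at a
stated spectrometer frequency (default 60 Hz — roughly half of k_off/2π
for the kinetics modelled here; no published cutoff exists, so the value
is configurable).

Di-ubiquitylated NCPs are handled by bookkeeping only: two equivalents of
ubiquitin per particle, binding assumed independent, so the site
concentration entering the isotherm is twice the particle concentration.

## Exchange lineshapes

The steady-state absorption spectrum of a two-site exchanging resonance is
computed by inverting the 2×2 complex Bloch–McConnell matrix at each grid
frequency, with pseudo-first-order rates k_fb = k_on·[L]_free (free-ligand
concentration from exact mass action) and k_bf = k_on·K_d. Detailed
balance holds by construction. The engine is validated pointwise (1e-6
relative) against an independent route — time-domain integration of the
coupled evolution with an adaptive high-order ODE solver followed by
Fourier quadrature — over 50 random parameter draws.

Only the ¹³C dimension is modelled (1-D traces); the ¹H multiplet
structure is absorbed into one free intensity scale per trace, mirroring
how experimental traces are rescaled for differential ¹H broadening.
Kinetic fitting holds K_d (from titrations) and intrinsic R2 values (from
linewidths) fixed; the per-trace scales are profiled out analytically,
leaving a 1-D bounded minimisation over log10(k_on). Synthetic defaults
for the unpublished R2 values are 40 s⁻¹ (free) and 80 s⁻¹ (bound),
ordinary methyl linewidths for particles of this size.

## Diffusion

I = I₀·exp(−aDG²). The composite constant `a` (gradient shape factors,
encoding length, diffusion delay) is an experimental input, never computed
from pulse-sequence timings — the encoding scheme is not part of this
package's contract. The synthetic default a = 2.3e3 s·cm⁻²·G⁻² gives
decays to ~15% of I₀ over a 2–48 G/cm grid at D = 3.4e-7 cm²/s, a typical
dynamic range. The nonlinear fit is cross-checked against the log-linear
slope; diffusion times are metadata carried with the series (different
species are measured with different delays, and sources disagree at the
50 ms level, so nothing is hard-coded).

## Triple-quantum methyl relaxation

I_a/I_b(T) = (3/4)·η·tanh(kT)/(k − δ·tanh(kT)), k = √(η²+δ²), with η the
intra-methyl ¹H–¹H cross-correlated rate and δ collecting external-proton
couplings. The macromolecular limit (ωτ_C ≫ 1) is assumed throughout —
appropriate for a ~250 kDa particle — and only the product S²τ_C is
estimated, via η = (9/10)(µ₀/4π)²γ_H⁴ħ²·S²τ_C/r_HH⁶ at r_HH = 0.1813 nm
(ideal methyl geometry, configurable). The closed form is validated
against its small-T linear limit (3/4)·η·T rather than against any
external implementation. Both fit modes are provided — η alone (δ pinned
to 0, appropriate in a deuterated background) and (η, δ) jointly — with
the joint fit as default. Ratios above the 3/4 plateau trigger a warning
when sporadic (noise) and rejection when systematic.

Synthetic ensembles default to S²τ_C ~ 18–32 ns per probe for the free
state (a flexible attachment to a slowly tumbling particle) and exactly
2-fold higher for the bound state; group comparison reports per-group
mean/sd (also the ML normal-density parameters) and the fold-change of
means.

## Restraint energies

All four terms return (energy, per-replica forces) with analytic
gradients; every term is finite-difference checked, replica-averaged terms
are permutation invariant, internal terms obey Newton's third law, and all
energies are non-negative and vanish exactly on the satisfied manifold.

* **Wall**: E = k(d−d_max)² for d > d_max on the mass-weighted COM
  distance of two active groups (mass weighting chosen where the
  geometric/mass-weighted choice was open). Shipped constants: k = 20
  kJ/(mol nm²), d_max = 2.5 nm.
* **NOE**: quadratic in the deviation from model distances; replica mode
  uses the slow-exchange effective distance (mean over replicas of r⁻⁶)^(−1/6),
  reducing exactly to the per-frame form at M = 1. β defaults to 0.25
  kJ/(mol nm²) in single-replica mode.
* **Chemical shift**: quadratic on the replica-mean back-calculated shift
  vs. target, for 5 backbone nuclei (Cα, C′, Hα, H_N, N) over a restrained
  window. The predictor is a pluggable interface; a deliberately trivial
  linear toy predictor (exact gradients) ships for testing the chain rule.
  No empirical shift predictor is reimplemented here.
* **Contacts**: S_i counts partner residues within r₀ of residue i
  (minimum inter-atom distance). Binary counting (s_ij ∈ {0,1}, "any atom
  pair" read as at-least-one) is used for reporting; the rational switch
  1/(1+(r/r₀)⁶) — continuous, value 1/2 at r₀ — for dynamics. Both
  published cutoffs (0.65 and 1.0 nm) are shipped as defaults. The
  "S_i ≥ 1 in at least one replica" condition is enforced through a
  one-sided quadratic on a log-sum-exp soft max over replicas (sharpness
  κ = 10 by default); because logsumexp/κ ≥ max, the penalty is exactly
  zero whenever any single replica satisfies the contact, matching the
  binary statement, while remaining differentiable.

Force constants ramp stepwise from zero: α 0→24 kJ/(mol ppm²) in steps of
1, β 0→2 kJ/(mol nm²) in steps of 0.1, k 0→50 kJ/(mol nm²) in steps of 1,
clamped at their endpoints.

## Annealing driver

BAOAB Langevin dynamics on coarse bead systems (≤ ~200 beads) under a
periodic piecewise-linear temperature profile: 300→500 K over 400 ps, hold
100 ps, 500→300 K over 400 ps, hold 100 ps — a 1 ns cycle, 50 cycles = 50
ns by default. Only the end-of-cycle low-temperature frames are flagged
for structural analysis. Defaults: dt = 0.01 ps, friction 2 ps⁻¹, bead
masses ~50–100 amu with harmonic bonds of ~100–1000 kJ/(mol nm²) — chosen
for stability at the default timestep, not copied from any all-atom
protocol, which would be meaningless for beads. The integrator is
deterministic given a seed; at constant temperature the sampled kinetic
temperature matches the thermostat target within 3% after the initial
transient (equipartition test).

The driver exists to exercise restraint mechanics end-to-end, e.g. the
anchoring-residue hand-off demonstration in `analysis/07_anneal_toy.py`:
a two-arm bead model with a single-occupancy pocket, where ramping up a
contact restraint on the competing arm displaces the initially bound one
over a few annealing cycles. This is a mechanism demonstration on a toy
analogue; it makes no claim about any atomistic system.

## Synthetic data: what it does and does not emulate

Generators draw from the exact forward models above with independent
Gaussian noise (the standard peak-position/intensity error model matching
the least-squares assumptions) and record truth in sidecar metadata kept
out of the measurement columns. They emulate: titration curvature with
ligand depletion, exchange-regime-dependent line broadening, G² decays,
tanh-type buildups, and the statistical spread of per-probe dynamics.
They do not emulate: raw FIDs or apodization artifacts, peak overlap and
picking errors, correlated baseline noise, temperature drift between
titration points, or partial-saturation effects — so passing recovery
tests demonstrate estimator correctness and precision at the stated noise
model, not robustness to every experimental pathology. Peak-position
uncertainty is not a published quantity; the 2% fractional default is a
plausible working value and is user-configurable.

## Problem sizes and numerics

Recovery statistics use 100 datasets (titrations, diffusion) or 20 probes
per group (relaxation), sizes that make the median/mean estimates stable
while keeping any single run in seconds. Optimizers are bounded
least-squares with multi-start where the objective can be multi-modal
(isotherms) and 1-D bounded search where it cannot (k_on). Degenerate
inputs are rejected early with named errors: flat traces, all-zero
gradient grids, fewer than 4 titration or 6 delay points, empty or
overlapping restraint groups, singular exchange matrices.

## Known limitations

Two-site exchange only (no 3-site, CPMG or CEST modelling); 1-D traces
only, not 2-D peak shapes; no separation of S² from τ_C; no Stokes–
Einstein mass inference from D; the annealing driver is not a force field
and cannot reproduce ensemble structure for a real solvated system; the
chemical-shift restraint requires an external predictor for physical use.
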