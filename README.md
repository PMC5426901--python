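# ubnmr

Quantitative analysis pipeline for methyl-TROSY NMR studies of a
ubiquitylated-nucleosome reader complex, exercisable entirely on synthetic
data. The package implements, as tested and reusable code, the chain of
analyses by which such a study turns peak lists and 1-D traces into
thermodynamic, kinetic, hydrodynamic and dynamical parameters, plus the
replica-averaged restraint potentials and simulated-annealing protocol used
to build a restrained structural ensemble.

It is aimed at NMR spectroscopists and integrative modellers who want the
individual steps — CSP mapping, isotherm fits, lineshape kinetics,
diffusion, triple-quantum relaxation, restraint energies — as importable,
property-tested functions rather than one-off scripts.

## What is computed

**Chemical-shift perturbations.** For each ILV methyl probe *i*,

    CSP_i = sqrt( Δδ_H,i² + Δδ_C,i² · w_i ),   w_i = σ_H,i / σ_C,i ≈ 0.16–0.18

with BMRB-derived per-methyl-type weights; probes with CSP more than 1σ
above the set mean are flagged as significantly perturbed.

**Equilibrium binding.** Fast-exchange shift changes follow the exact 1:1
quadratic isotherm (ligand depletion included),

    Δδ′ = Δδ′_MAX · ( [L]T+[P]T+K_d − sqrt(([L]T+[P]T+K_d)² − 4[P]T[L]T) ) / (2[P]T)

fitted per residue; a nucleosome carrying one ubiquitin on each H2A copy
contributes two independent sites, so [P]T = 2 × [NCP].

**Exchange kinetics.** 13C-dimension traces in intermediate exchange are
simulated by a 2×2 complex Bloch–McConnell matrix inversion and fitted for
k_on at fixed K_d and fixed intrinsic R2, with one intensity scale per
trace; k_off = k_on·K_d.

**Diffusion.** Gradient-encoded intensities follow I = I₀·exp(−aDG²);
nonlinear and log-linear estimators are cross-checked.

**Methyl dynamics.** Intra-methyl ¹H–¹H triple-quantum buildup ratios
follow the closed form (3/4)·η·tanh(kT)/(k − δ·tanh(kT)), k = √(η²+δ²),
with η ∝ S²τ_C through the dipolar prefactor at r_HH = 1.813 Å.

**Restraint energies.** Flat-bottom COM wall, r⁻⁶ replica-averaged NOE,
replica-mean chemical-shift, and "at least one replica in contact"
potentials, all with analytic gradients validated against finite
differences, plus the published force-constant ramps (0→24, 0→2, 0→50) and
the 300/500 K annealing cycle driven by a BAOAB Langevin integrator on
coarse bead systems.

## Worked example

```python
import numpy as np
from ubnmr import SyntheticConfig, fit_kd
from ubnmr.synthetic import generate_titration
from ubnmr.isotherm import ncp_site_concentration

sites = ncp_site_concentration(50.0)          # 50 µM particle -> 100 µM sites
cfg = SyntheticConfig(seed=7, noise_sd=0.02, true_params={"kd_uM": 24.0})
series = generate_titration(cfg, np.linspace(0, 2.6, 16), sites)
fit = fit_kd(series)
print(f"K_D = {fit.kd_uM:.1f} ± {fit.kd_sd_uM:.1f} µM")
```

prints

    K_D = 24.3 ± 3.8 µM

the dissociation constant recovered from a 16-point titration generated at
24 µM with 2% shift noise, with the spread of per-residue fits as the
uncertainty.

The full analysis narrative lives in `analysis/` as numbered drivers — run
them in order from the repository root:

```sh
python analysis/01_simulate_datasets.py   # all synthetic inputs + truth sidecars
python analysis/02_fit_binding.py         # K_D 24 / 956 µM, ~40-fold enhancement
python analysis/03_fit_kinetics.py        # k_on ~ 2.4e7 M^-1 s^-1 from lineshapes
python analysis/04_fit_diffusion.py       # D ~ 3.4e-7 cm^2/s
python analysis/05_fit_relaxation.py      # S2·tauC distributions, 2-fold change
python analysis/06_restraint_energies.py  # restraint terms + ramp endpoints
python analysis/07_anneal_toy.py          # anchoring hand-off on a toy model
```

Each writes its tables under `results/`. A `ubnmr` command-line interface
exposes the same stages (`ubnmr simulate titration`, `ubnmr fit-kd`, ...).

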