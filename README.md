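# ionbind

Analysis toolkit for divalent-metal binding to EF-hand proteins, built
around the characterization of Zn²⁺/Ca²⁺/Mg²⁺ binding to neuronal calcium
sensor-1 (NCS-1): a small myristoylated sensor with three functional
EF-hands (EF2–EF4) whose conformation and stability shift as magnesium,
calcium and zinc compete for its sites.

The package provides four analyses plus seeded generators that emulate the
corresponding experiments:

1. **Geometric Zn²⁺-site prediction** (`ionbind.sites`). Candidate
   chelator atoms (SG, ND1, NE2, OD1, OD2, OE1, OE2, OG, OG1, OH and the
   backbone carbonyl O) are grouped into cliques of ≥ 3 atoms mutually
   within 6 Å; a 0.1 Å grid counts, per voxel, the chelators at
   1.7–3.0 Å; voxels inside van der Waals spheres are removed; connected
   blobs of feasible cation positions are ranked by their maximum count.
2. **ITC binding models** (`ionbind.itc`). Simulation and nonlinear
   least-squares fitting of integrated titration isotherms under the
   *one set of sites*, *two sets of sites* and *sequential binding*
   models. For any model the free-ligand concentration x solves the mass
   balance X_t = x + M_t·B(x), with B(x) from the binding polynomial;
   the per-injection heat is the increment of Q = V₀·M_t·H̄(x) with the
   standard overflow-cell displacement correction. Secondary
   thermodynamics follow from ΔG = −RT ln K_a and ΔS = (ΔH − ΔG)/T.
3. **Equilibrium dialysis** (`ionbind.dialysis`). Bound-per-protein
   stoichiometry from paired-chamber totals and Hill fits
   B(f) = B_max·fʰ/(K_halfʰ + fʰ).
4. **Thermal stability** (`ionbind.thermal`). Log-normal (Siano–Metzler)
   fits of tryptophan emission spectra (λ_max, I_max); Boltzmann sigmoid
   fits of λ_max(T) melt curves; derivative-based T_m from I350/I330
   ratio scans and T_agg from 350 nm light-scattering rises.

## Worked example

Simulate a zinc titration at the study conditions (25 μM protein in a
200 μL cell, 30 × 2 μL injections of 500 μM Zn²⁺) under the two-sets
model, refit it, and derive the thermodynamics of the high-affinity set:

```python
import numpy as np
from ionbind import (TitrationProtocol, TwoSetsParams, simulate_isotherm,
                     fit_isotherm, derive_thermo)

protocol = TitrationProtocol.itc200(protein_conc=25e-6, syringe_conc=500e-6)
truth = TwoSetsParams(n1=0.7, k_a1=2.3e5, dh1=-11.8,
                      n2=2.0, k_a2=9.2e6, dh2=-7.3)
iso = simulate_isotherm(protocol, truth, noise_sd=0.05, seed=1)
fit = fit_isotherm(iso, protocol, "two_sets", seed=1)
high = max((fit.params.k_a1, fit.params.dh1), (fit.params.k_a2, fit.params.dh2))
state = derive_thermo(high[0], high[1], temperature=298.15)
print(f"K_a(high) = {high[0]:.3g} M^-1, K_d = {state.k_d*1e6:.2f} uM, "
      f"dG = {state.dg:.2f} kcal/mol")
```

```
K_a(high) = 8.49e+06 M^-1, K_d = 0.12 uM, dG = -9.45 kcal/mol
```

The fitted high-affinity constant lands near the generating 9.2 × 10⁶ M⁻¹
(sub-micromolar K_d); ΔG ≈ −9.5 kcal/mol is the corresponding binding
free energy at 25 °C.

The same analyses are available from the command line:

```sh
ionbind generate dialysis --seed 5 -o gen/
ionbind fit-dialysis gen/wells.tsv -o hill.json
ionbind thermo --ka 3.32e4 --dh -3.0 --temp-c 25
ionbind generate structure --seed 11 -o toy/ && ionbind predict-sites toy/toy.pdb
```

`fit-dialysis` on the wells generated with seed 5 prints
`K_half = 4.44 uM, B_max = 1.44` — half-maximal zinc binding at
micromolar free zinc, with about one and a half zinc ions bound per
protein at saturation (the generating truth is 4.7 μM and 1.5; this is
one 5%-noise replicate). The `thermo` call prints
`dg_kcal_per_mol = -6.17` (−6.2 at one decimal) for the D2R-peptide
interaction.

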