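# Methods

This note records the models implemented in `ionbind`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know about.

## Geometric zinc-site prediction

**Model.** A divalent cation binds where several protein chelator atoms
can ligate it simultaneously. The search is purely geometric:

1. *Coordinators* are atoms named SG, ND1, NE2, OD1, OD2, OE1, OE2, OG,
   OG1, OH, plus the backbone carbonyl oxygen "O" of standard residues
   (waters are excluded from site search but allowed in
   `coordination_shell`, where crystallographic waters legitimately
   complete a shell).
2. *Cliques*: coordinators mutually closer than `clique_pair_max` (6 Å),
   in sets of at least `clique_min_size` (3), found as maximal cliques of
   the coordinator graph. Maximal cliques (rather than all ≥3-subsets)
   are used because every sub-clique's members are already members of
   some maximal clique, so the union of member atoms — the only thing the
   density stage consumes — is identical and the enumeration far cheaper.
3. *Density*: on a cubic grid of step 0.1 Å spanning the clique atoms
   padded by `d_max`, each voxel counts the coordinators at distance
   within [`d_min`, `d_max`] = [1.7, 3.0] Å. The 3 Å cap is the observed
   maximum cation–chelator contact; the 1.7 Å floor is about the shortest
   Zn–O/Zn–S bond, below which the cation would clash with its own
   ligand. Counts below 3 are zeroed — fewer simultaneous chelators do
   not make a site.
4. *Van der Waals exclusion* removes voxels inside any heavy atom's
   sphere (Bondi radii by default, table overridable; an element missing
   from the table is a configuration error, not a silent skip).
5. *Ranking*: surviving voxels are merged into 26-connected components;
   each is one predicted site, ranked by maximum count, ties by voxel
   count, then by peak coordinates.

**Peak placement.** Ideal shells produce flat-topped count plateaus
(every voxel from which all chelators are in range has the same count),
and the plateau can be asymmetric: for an incomplete octahedral shell it
extends toward the missing vertex, where no `d_min` constraint applies.
Among tied peak voxels the package therefore prefers the most
*symmetric* coordination — the voxel minimizing the standard deviation
of its chelator distances (quantized at half a grid step so that grid
noise cannot dominate), since a cation at the center of a shell sits at
near-equal distance from every ligand. Remaining ties fall back to the
distance to the plateau centroid, then to lexicographic order, keeping
the output fully deterministic. A plain lexicographic tie-break was
rejected because it parks the peak at a plateau corner, up to
`min(r − d_min, d_max − r)` ≈ 0.6 Å from the true center.

**Angles.** Surveyed coordination-angle distributions are not part of the
default score; `GeometryParams.angle_window` reserves the hook. Distances
alone already confine the density to genuine multi-chelator pockets, and
inventing an angular distribution without data would be arbitrary.

**Limits.** The grid is O((size/step)³); a `max_voxels` budget (default
1.2 × 10⁸) rejects runs that should use a coarser step. Coordinates are
used in the file's native frame; no symmetry expansion is performed.

## ITC binding models

For free-ligand concentration x, the bound-per-protein function B(x) is

* one set: n·Kx/(1+Kx);
* two sets: n₁·K₁x/(1+K₁x) + n₂·K₂x/(1+K₂x);
* sequential: (Σᵢ i·βᵢxⁱ)/(1+Σᵢ βᵢxⁱ), βᵢ = K₁⋯Kᵢ (stepwise macroscopic
  constants; trailing zeros truncate the polynomial).

After injection i the cell totals follow the discrete overflow dilution
M_t(i) = M_t(0)·∏ⱼ(1 − dVⱼ/V₀) (at 2 μL into 200 μL the discrete and
exponential forms differ by < 0.1%; the discrete form matches
per-injection integration). x solves X_t = x + M_t·B(x) — Brent's method
for the public scalar call, an 85-step vectorized bisection (machine
precision) in the simulation/fitting hot path. The measured heat is
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2 with Q = V₀·M_t·H̄(x), reported
per mole of injectant in kcal/mol. Competition experiments are fitted as
apparent constants under the same models with the competitor recorded as
metadata; no ternary model is attempted. A first-injection discard is
available but off by default.

**Fitting** uses variable projection: for fixed capacities and
association constants the model is linear in the stepwise enthalpies, so
the enthalpies are profiled out exactly by linear least squares inside a
bounded `least_squares` over (N, log₁₀K). Eight starts over K =
10³–10⁹ M⁻¹ (seeded jitter on capacities) guard against the multi-modal
sequential likelihood; unweighted residuals are used (integrated-peak
noise is approximately homoscedastic). Errors come from the Gauss–Newton
covariance at the optimum. A flat isotherm is flagged non-converged
rather than raising. Identifiability caveat: at high c = nK·M_t (≫ 100)
the isotherm approaches a step and the data only bound K from below, so
single-fit association constants scatter widely — medians over seeds are
the meaningful recovery statistic, as in the acceptance studies.

**Thermodynamics.** ΔG = −RT ln K_a with R = 1.98720 × 10⁻³ kcal K⁻¹
mol⁻¹, K_d = 1/K_a, ΔS = 1000·(ΔH − ΔG)/T cal K⁻¹ mol⁻¹.

## Equilibrium dialysis

Bound-per-protein = (protein-side total − buffer-side total)/[protein];
the buffer-side total is the free concentration (free metal equilibrates
across the membrane). Negative computed bound values — possible from
assay noise near zero binding — are clipped to 0 and flagged rather than
propagated. The Hill fit floats B_max, K_half and h by default (h is not
reported by typical dialysis analyses, so it is exposed rather than
assumed); with sparse curves h and K_half are strongly correlated and
`h_fixed=1` pins the non-cooperative value.

## Thermal stability

Spectra use the Siano–Metzler log-normal band (position, height, FWHM,
asymmetry ρ > 1; ρ → 1 recovers a Gaussian of the same FWHM); λ_max and
I_max are read from the fitted curve, and a peak within 2% of the scan
edge is flagged unreliable. Melt curves use the two-state Boltzmann
sigmoid with linear native/denatured baselines, fitted by the same
variable-projection trick (baselines are linear parameters). The
derivative methods smooth with a 5-point moving average (appropriate for
~0.1–0.5 K sampling at ~1 K/min scan rates), take a central-difference
derivative, and report the temperature of the extremal |d/dT| (ratio
curves; sign-agnostic because instruments report either intensity-ratio
ordering) or of the maximal signed rise (scattering). Ties resolve to
the lowest temperature; a flat or monotone-featureless curve sets a
no-transition flag. Temperatures are °C externally, K only inside the
thermodynamic relations.

## Synthetic generators

All generators are pure functions of (seed, parameters) and write ground
truth beside their data. Defaults encode the study conditions: 25 μM
protein in a 200 μL cell titrated by 2 μL injections of a 375–750 μM ion
syringe; dialysis over 2–150 μM free zinc (8-point log grid) at ~5 μM
protein with Hill truth (B_max 1.5, K_half 4.7 μM, h 1); melt scans
15–95 °C at 0.5 °C with an apo transition at 40 °C of 3 °C width between
338 and 352 nm baselines; chelation shells at 1.8–3.0 Å in tetrahedral or
octahedral geometry with decoy carbons ≥ 5 Å out (standard-residue
naming, so coordinator selection is exercised, not bypassed).

Noise is additive Gaussian throughout, with scale conventions chosen to
match each instrument's dominant error: ITC — fraction of the largest
clean per-injection heat (integration noise is absolute per peak);
dialysis — multiplicative on the bound amount (atomic-absorption error is
relative per measurement); melt curves — fraction of the transition
amplitude (reported λ_max scatter is a fraction of the ~14 nm unfolding
shift; a fraction of the ~340 nm absolute wavelength would be physically
meaningless).

What the generators do **not** emulate: baseline drift and peak-shape
artifacts in thermograms, Donnan corrections and assay calibration in
dialysis, aggregation tails and multi-transition unfolding in melts,
conformational heterogeneity or crystallographic disorder in structures.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated noise models, not robustness to every
instrumental artifact of real data.

## Recovery studies (`ionbind.benchmarks`, `scripts/acceptance.py`)

Each study simulates 20 seeded replicates at the study's fitted
parameters, refits with the matching model, and reports medians:
dialysis Hill parameters (5% noise); titrations of Ca²⁺ (sequential,
three sites), Zn²⁺ (two sets) and Mg²⁺ (one set) at 1% heat noise with
repeated 2 μL injections continued past saturation to molar ratio ~11
(45 injections at 500 μM syringe, 30 at 750 μM — the schedule a syringe
refill produces); a long post-saturation baseline is what pins the
association constants at high c = nK·M_t, where the isotherm corner
carries little curvature information. Apo melt curves are fitted at 1%
amplitude noise. Problem sizes were chosen
to make each study a minutes-scale desk computation while leaving the
median estimates stable. Seeds are spawned from a single base seed via a
seeded integer draw, so every study is reproducible end to end.
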