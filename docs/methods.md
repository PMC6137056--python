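# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Ensemble geometry

An NMR "structure" is a bundle of m conformers; its precision is summarized
by the spread about a mean structure.  The mean is defined iteratively:
superpose every conformer onto the current mean over the stated selection
(Kabsch least squares, uniform weights, proper rotations only), recompute
the coordinate-wise mean, and repeat until the mean moves less than 1e-6 Å
(max 100 iterations; convergence is rapid because the update is a fixed
point of the least-squares functional).  The reported ensemble RMSD is the
**mean over conformers of each conformer's RMSD to the converged mean**, the
convention of CYANA and MOLMOL.  Because the literature is split, the
root-mean-square combination (`combine="rms"`) and the average-pairwise RMSD
are first-class options; for Gaussian bundles the conventions differ by a
factor near √(2m/(m−1)) between model-to-mean and pairwise.

Atom sets: `backbone` = {N, CA, C} (carbonyl O excluded), `heavy` = all
non-hydrogen atoms.  Residue ranges are author-numbered and inclusive on
both ends.  Per-element RMSDs default to element-local superposition (the
element's own residues define the fit); global-superposition values are
available because published element statistics rarely say which was used.
Per-residue profiles use one global superposition on a stated reference
selection, then per-residue RMS deviations from the mean; with the `rms`
combination the profile aggregates exactly (atom-count-weighted) to the
selection RMSD, which the suite asserts to 1e-9.

For iid coordinate noise σ per atom, the model-to-mean RMSD concentrates at
σ√3·√((m−1)/m); the suite uses this closed form as a simulation oracle.

Single-model distance queries default to MODEL 1 of the file (the
"representative" conformer of most deposits); the model index is an
argument everywhere.

## Restraint bookkeeping

CYANA-style upper-limit lines (`resnum resname atom resnum resname atom
bound`) are classified by sequence separation: intraresidue (i = j),
sequential (|i−j| = 1), medium (2 ≤ |i−j| ≤ 4), long (≥ 5) — the standard
NMR convention; only the first two are universally printed, the medium/long
split follows common usage.  Explicit hydrogen-bond restraints (marked
`#hbond`) keep their own category so distance categories always partition
the distance-restraint total.  The `pdb_mr` dialect extracts CYANA-format
lines from a deposited MR file and ignores everything else; a count
disagreement with a published table would be reported by the acceptance
test, not silently reconciled.

## ¹⁵N relaxation

Decay series are fitted with I(t) = I₀·exp(−Rt) by Levenberg–Marquardt,
seeded from a log-linear regression on the positive intensities.
Intensities are normalized by their maximum before fitting, which makes the
estimated rate exactly invariant under intensity rescaling.  Inversion
recovery data acquired without magnetization inversion to a clean
two-parameter form can use the three-parameter model A + B·exp(−Rt)
(`model="inv_recovery"`); the two-parameter form is the default because
pseudo-3D peak-height series are conventionally reduced that way.

Uncertainties: σ_R is the larger of the covariance estimate and a
Monte-Carlo estimate that resamples the fitted curve with the duplicate-
delay noise (RMS of paired differences ÷ √2, pooled over residues — the
purpose of recording starred delays twice).  The delay schedules shipped as
defaults are the experimental ones: T1 50–1020 ms (200, 600 ms duplicated)
and CPMG T2 10–190 ms (50, 110 ms duplicated).

Region statistics are mean ± SD (n−1) over residues inside the stated
ranges after exclusions (prolines, overlapped peaks).  R₂/R₁ is computed
per residue and averaged, never as a ratio of averages, with first-order
error propagation.  Flexibility labels: a residue is "flexible" when its
NOE falls below 0.65 or its R₂/R₁ below 0.75× the structured-region median;
both thresholds are parameters, chosen as round values that separate the
loop from the core in profiles with the contrast this system shows
(structured NOE ≈ 0.87 vs loop ≈ 0.64).

## CSP mapping

Peaks are paired strictly by assignment label — never nearest-neighbour in
ppm space, since assignments exist for both states.  The combined shift is
√(ΔH² + (ΔN/10)²); the factor 10 reflects the ~10× wider backbone ¹⁵N shift
range and is configurable for other nuclei.  Signs are bound − free;
only magnitudes enter the CSP, so it is symmetric under swapping states.

No community-standard numeric significance rule exists, so the default is
mean + 1·SD with a 0.01 ppm floor, recorded in the output metadata
(`DataFrame.attrs["threshold"]`) so the rule is never silent; raising k is
provably monotone (can only unflag).  Structural annotation reports minimum
Cα-to-site distances and single-linkage clusters at 8 Å Cα–Cα, a scale at
which contiguous binding surfaces merge and remote spurious flags stay
separate.

## Triad search

The motif is nucleophile–base–acid: Ser OG, His imidazole, Glu/Asp
carboxylate or Thr hydroxyl.  Geometry: OG within d₁ of one imidazole
nitrogen and an acceptor within d₂ of the *other* nitrogen (distinct
nitrogens enforced; both ND1/NE2 role assignments tried because the
tautomer is unknown without pKa work).  Default d₁ = d₂ = 4.0 Å — a
hydrogen bond (≈2.7–3.2 Å heavy-atom) plus slack for coordinate
uncertainty in an NMR ensemble; the realized distances are always in the
report so stricter readings can be applied post hoc.  Enlarging either
cutoff never removes a candidate, and the candidate set is rigid-motion
invariant (both are property-tested).

Ensemble handling: candidates can be required to recur in at least
⌈m/2⌉ conformers (configurable), since a contact that appears in one
conformer of ten is ensemble noise.

Solvent exposure, used to rank otherwise-equal candidates and to reject a
solvent-protruding acid partner, is Shrake–Rupley accessible surface area:
probe 1.4 Å, 92 golden-spiral points per atom, element van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å).  The implementation is in-package so
the point set and radii are explicit; an isolated atom reproduces
4π(r+1.4)² within 2% at 92 points (analytic oracle) and the per-atom areas
agree with an independent library implementation at matched radii.
Relative side-chain exposure divides the side chain's in-structure area by
the same side chain's area recomputed in isolation.  This
conformation-matched reference (rather than tabulated Gly-X-Gly extended
areas) makes an unoccluded residue score exactly 1 and keeps the measure
internally consistent across nonstandard conformers; values can slightly
exceed 1 only through the finite point sampling.

## Thermodynamic fits

**Melt.**  The fraction curve is computed exactly as
(θ_t − θ_U)/(θ_F − θ_U).  As written this ratio is 1 in the folded state,
i.e. it is the folded fraction; the complement is exposed
(`complement=True`) and the package computes the printed formula without
deciding which the original analysis intended.  The transition is fitted as
a Boltzmann sigmoid with constant (optionally linear) baselines; Tm is the
temperature where the transition fraction is ½.  A curve whose total
amplitude is under six times the point-to-point noise is rejected as
transition-free rather than fitted.  The van 't Hoff enthalpy implied by
the fitted width (ΔH = RT_m²/width) is reported but flagged as derived.

**Gel shift.**  y = V_max·x/(K_d + x), seeded with V_max ≈ 1.2·max(y) and
K_d at the half-saturation abscissa (exact model property).  The "R value"
is the Pearson correlation of observed vs fitted intensities, matching how
such fits are conventionally reported.  With only three titration points in
triplicate the design is sparse, so recovery statements are about replicate
medians.

**ITC.**  Sequential (interacting) two-site model in the standard MicroCal
formulation.  Displaced-volume bookkeeping:
M_t = M₀(1−v/2V₀)/(1+v/2V₀), X_t = X₀(v/V₀)/(1+v/2V₀).  Free ligand solves
X_t = [X] + M_t(K₁[X] + 2K₁K₂[X]²)/P by Brent bisection on [0, X_t]
(residual < 1e-12·X_t; bisection is preferred over Newton because the mass
balance is monotone and bracketing cannot diverge).  Per-injection heat is
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (dVᵢ/V₀)(Qᵢ+Qᵢ₋₁)/2 plus a fitted constant dilution
offset (blank subtraction is supported upstream).  With the volume
correction off, heats telescope exactly to the final cumulative Q, which is
asserted to 1e-10.  At K₂ = 0 the model equals the closed-form single-site
(Wiseman) isotherm to 1e-6 relative (oracle test).  Fitting is multi-start
bounded least squares over (log₁₀K₁, log₁₀K₂, ΔH₁, ΔH₂[, offset]) with K
starts on a half-decade grid from 10³ to 10⁸ M⁻¹; a c-value far outside
[1, 1000] triggers an ill-conditioning warning.  The "effective K_d" is
1/K of the tighter step.

## Synthetic data

Each generator draws from `default_rng(SeedSequence(seed,
spawn_key=(crc32(tag),)))` — one stream per stage, so adding a stage never
shifts another stage's fixtures, and identical arguments give byte-identical
files.

The toy ensemble is a smooth Cα trace (10-residue helix at 1.5 Å rise /
2.3 Å radius / 100°·residue⁻¹, two 6-residue strands, a 23-residue loop arc
— the element sizes of the fold under study) with fixed local offsets for
N, C, O, CB, CG, plus iid Gaussian coordinate noise, σ_core in the
helix/strands and σ_loop in the loop.  Defaults σ_core = 0.3 Å,
σ_loop = 1.5 Å give an ordered-region backbone spread of ≈0.5 Å and a
loop/core per-residue contrast of ≈5×, the regime of a well-determined
small-protein ensemble with one mobile loop.  It is a statistical fixture,
not a physical model: no covalent geometry, no packing, no anisotropic
order parameters — so passing geometry tests demonstrates correctness of
the estimators, not realism of the noise model.

Decay fixtures are exact exponentials on the experimental delay schedules
with relative Gaussian intensity noise (default studies use 2%, a typical
peak-height noise level); titration fixtures perturb a chosen residue
subset by (ΔH, ΔN) with random signs, with optional ppm jitter elsewhere;
melt/binding/ITC fixtures are generated from the same models the fitters
estimate, which is exactly what a parameter-recovery test requires and
exactly why such tests cannot detect model misspecification in real data.
The calorimetric fixture uses the measurement geometry (1.445 mL active
cell volume — the VP-ITC's nominal value, 75 µM macromolecule, 2 mM ligand,
28 × 5 µL injections).

## Problem sizes

The suite and the acceptance script size their simulations for minutes on a
single CPU as a deliberate design point: 500 transverse-rate and 200
longitudinal-rate recoveries, 12 gel-shift replicates, 5 calorimetric
replicates, 10-conformer ensembles with ~45 residues, triad fixtures with
up to 20 decoys.  These are the smallest sizes at which the medians being
asserted are stable across seeds.

## Known limitations

- No model-free (Lipari–Szabo) analysis, CPMG dispersion, or spectral
  processing; intensities are taken as tabulated.
- No K_d extraction from CSP trajectories; affinity comes from the
  gel-shift and calorimetric fits.
- The triad search is purely geometric: no electrostatics, no pKa
  modelling, no activity prediction.
- The relative-exposure reference is the residue's own isolated side chain,
  not a tabulated extended-tripeptide area; values are comparable within a
  structure and across conformers, less so against literature relative-ASA
  tables.
- The deposited-reference acceptance checks (ensemble statistics, the 1254
  restraint count, the S114–H95–T116/E80 triad geometry) require the
  deposited entry as local files under `data/deposited/`; the package does
  not download or redistribute it.
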