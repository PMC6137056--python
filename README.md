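# bolakit

Structure–function analysis for solution-NMR studies of BolA-like DNA
endonucleases (and similar small α/β proteins): ensemble geometry statistics,
backbone ¹⁵N relaxation, chemical-shift-perturbation (CSP) mapping of ligand
binding, geometric catalytic-triad prediction, and the thermodynamic curve
fits that accompany such studies (CD thermal unfolding, gel-shift binding,
ITC).  Every stage has a seeded synthetic-data generator, so the whole
pipeline is testable without downloading anything.

## Who this is for

Solution-NMR and structural-biology groups who have: a multi-model PDB
ensemble (e.g. the 10-conformer bundle of a CYANA/CNS calculation), CYANA
`.upl` distance-restraint lists, per-residue relaxation decay tables, amide
peak lists for free and ligand-bound states, and CD melt / densitometry /
calorimetry curves — and who want the standard derived quantities computed
reproducibly instead of by a chain of one-off scripts and instrument
software.

## What it computes

**Ensemble geometry.** Conformers are least-squares superposed
(Kabsch) onto an iteratively converged mean structure; the ensemble RMSD is
the mean over conformers of each conformer's RMSD to that mean
(CYANA/MOLMOL convention; average-pairwise is available).  Per-residue and
per-element (helix/strand) profiles, plus Cα–Cα distance queries.

**¹⁵N relaxation.** Rates from two-parameter exponential fits
I(t) = I₀·e^(−Rt) (three-parameter inversion recovery available), with
uncertainties from the fit covariance or Monte-Carlo resampling using the
noise estimated from duplicate delays.  Heteronuclear NOE = I_sat/I_eq with
propagated error, per-residue R₂/R₁, and mean ± SD region statistics
(structured core vs flexible loop) with proline/overlap exclusions.

**CSP mapping.**  Δδ = √(ΔH² + (ΔN/10)²) ppm from label-paired peak lists;
significance by mean + k·SD with an absolute floor (defaults k = 1,
0.01 ppm, fully exposed in output metadata); flagged residues are placed in
spatial context on the structure (8 Å single-linkage Cα clusters, distances
to a site of interest).

**Catalytic-triad search.**  For every Ser OG, His imidazole nitrogens
within a hydrogen-bond-like cutoff (default 4.0 Å), and a Glu/Asp/Thr
acceptor within the cutoff of the *other* nitrogen — both tautomer role
assignments tried, realized distances always reported.  Conformer-consensus
filtering over an ensemble, and ranking with a side-chain solvent-exposure
tie-break (Shrake–Rupley, probe 1.4 Å, 92 points), which separates a buried
acid partner from a solvent-protruding one.

**Thermodynamics.**  Two-state CD melt: f(T) = (θ_t−θ_U)/(θ_F−θ_U), Boltzmann
sigmoid, Tm at f = 0.5.  Gel-shift titration: y = V_max·x/(K_d + x), with the
fit's observed-vs-fitted correlation R.  ITC: sequential two-site isotherm
with binding polynomial P = 1 + K₁[X] + K₁K₂[X]², cumulative heat
Q = V₀·M_t·(ΔH₁F₁ + (ΔH₁+ΔH₂)F₂), free ligand solved per injection by
bisection, MicroCal displaced-volume correction, multi-start least squares;
at K₂ = 0 it reduces to the closed-form single-site (Wiseman) isotherm.

## Worked example

Generate a full synthetic input bundle and run the pipeline on it:

```bash
bolakit simulate all --seed 11 --out demo
cat > demo/config.yaml <<EOF
inputs:
  ensemble_pdb: demo/ensemble.pdb
  t1_table: demo/t1_decays.tsv
  t2_table: demo/t2_decays.tsv
  noe_table: demo/noe_table.tsv
  peaks_free: demo/peaks_free.tsv
  peaks_bound: demo/peaks_bound.tsv
  melt_csv: demo/melt.csv
  binding_csv: demo/binding.csv
  itc_csv: demo/itc.csv
params:
  structured_ranges: "34-49,73-78"
  loop_range: "50-72"
output_dir: demo/run
EOF
bolakit pipeline run --config demo/config.yaml
```

prints (seed 11):

```
bolakit run summary
===================
ensemble RMSD (ordered region): backbone 0.47 A, heavy 0.48 A
relaxation (structured): R1 1.15 +/- 0.15 s-1, R2 13.52 +/- 0.86 s-1
relaxation (loop): R1 1.71 +/- 0.16 s-1, R2 10.72 +/- 0.99 s-1
hetNOE: structured 0.89 +/- 0.05, loop 0.64 +/- 0.14
significant CSPs: 11 residues (35, 37, 49, 50, 57, 58, 59, 76, 79, 118, 119)
thermal unfolding: Tm = 54.0 C
EMSA: Kd = 0.88 uM (R = 0.98)
ITC (sequential sites): K1 = 3.23e+05 /M, K2 = 2.39e+04 /M, effective Kd = 3.09 uM
```

Reading it: the synthetic conformer bundle was built with 0.3 Å core noise,
so the ordered-region ensemble RMSD lands near 0.5 Å; the loop residues were
generated with higher R₁ and lower R₂ than the core, and the region averages
recover that contrast; the titration perturbed exactly the eleven listed
residues and the mean + 1·SD rule flags exactly those; the melt was
generated at Tm = 54 °C and the binding curve at K_d = 1.1 µM.  Each line is
traceable to a stage CSV in `demo/run/`, and `provenance.json` echoes every
parameter the run used, defaults included.

Individual stages are also available directly (`bolakit ensemble-rmsd`,
`residue-rmsd`, `distance`, `relax-fit`, `csp`, `triad-scan`, `melt-fit`,
`bind-fit`, `itc-fit`, `restraints`), and everything the CLI does is a thin
wrapper over importable functions (`bolakit.geometry`, `bolakit.relaxation`,
`bolakit.csp`, `bolakit.triad`, `bolakit.thermo`, `bolakit.synth`).

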