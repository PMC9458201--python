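# cdbind

A desk-scale toolkit for host–guest (cyclodextrin) binding analysis. It
implements the full estimator chain behind an absolute-binding-free-energy
study without requiring any simulation engine or spectrometer:

- **`cdbind.noneq`** — free-energy estimation from bidirectional
  non-equilibrium work samples: the maximum-likelihood (Bennett/Crooks)
  self-consistency solver, one-sided exponential averaging as a diagnostic,
  stratified bootstrap uncertainties, and a Bhattacharyya overlap
  coefficient between forward and mirrored-reverse work distributions.
- **`cdbind.restraints`** — the closed-form standard-state free energy of
  six harmonic orientational restraints (distance, two angles, three
  dihedrals), dispersion-based restraint selection from coordinate traces
  (circular statistics for dihedrals), equipartition inversion to force
  constants, four-leg thermodynamic-cycle assembly, and replica averaging
  with root-sum-square error propagation.
- **`cdbind.ensemble`** — pairwise superposition RMSD (Kabsch), greedy
  neighbor-count (gromos/Daura-style) clustering under an RMSD cutoff,
  representative selection, and per-structure end-point binding-energy
  decomposition (`complex − host − guest`) with mean ± sample-std summaries.
- **`cdbind.nmr`** — three-parameter inversion-recovery T1 fitting
  (`B + F·exp(−x·G)`, `T1 = 1/G`), the tabulated T1 percentage-change
  metric, Stejskal–Tanner log-linear diffusion fitting, and
  chemical-shift-perturbation tabulation/ranking.
- **`cdbind.titration`** — Benesi–Hildebrand double-reciprocal fitting of
  1:1 fluorescence titrations, a direct nonlinear isotherm fit (optionally
  with exact mass balance), and a linearity-based stoichiometry check.
- **`cdbind.synthetic`** — seeded generators for every input above with
  known ground truth: Crooks-consistent Gaussian work pairs, 1:1 binding
  isotherms, inversion-recovery and gradient-decay curves, clustered toy
  conformer ensembles, and harmonic restraint traces.
- **`cdbind.datasets`** — small bundled reference tables (per-replica free
  energies, T1 pairs, chemical shifts) used by the acceptance checks.

Units: energies in kcal/mol (k_B = 1.987204e-3 kcal/mol/K), distances in Å,
angles in degrees at API boundaries. Reverse works are stored as work along
the reverse transition, so `−W_rev` estimates ΔG from the reverse side; the
convention is written into every generated file header.

## CLI

```bash
cdbind simulate --kind work --dg-true -5.09 --sigma-w 1.0 --n-per-side 200 --seed 1 --out work.tsv
cdbind estimate --work-file work.tsv --n-boot 1000 --seed 0 --json-out est.json
cdbind cycle --legs legs.json --replicas replicas.tsv
cdbind nmr t1   --input recovery.csv
cdbind nmr dosy --input decay.csv
cdbind nmr shifts --free free.csv --complex complex.csv
cdbind titration --input titration.csv --fit both
```

`simulate` also produces titration (`--kind titration`), inversion-recovery
(`t1`), gradient-decay (`dosy`), toy-ensemble (`ensemble`) and
restraint-trace (`restraint`) fixtures; every file records its ground truth
in `# key=value` header lines. `estimate` accepts either two-column work
files or per-snapshot dH/dλ traces (`--dhdl`), which are integrated by the
trapezoid rule.

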