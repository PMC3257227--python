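# ribodyn

Residue-resolved stability and dynamics analysis for small globular
proteins, built around five experiment families and their synthetic
ground-truth generators:

- **hx_kinetics** — H/D exchange: first-order decay fits of peak height vs.
  time, intrinsic (random-coil) rate prediction from a shipped
  nearest-neighbour parameter set, protection factors `P = k_rc/k_obs`,
  opening free energies `dG_op = RT ln P`, EX1/EX2 regime discrimination.
- **relaxation** — amide 15N dynamics: Lipari–Szabo model-free forward
  model (dipolar + axially symmetric CSA, `r_NH = 1.02 A`,
  `delta_sigma = -160 ppm`), two-stage global-correlation-time fit with
  Monte-Carlo confidence bounds, reduced spectral-density mapping
  (`J(0), J(wN), J(0.87 wH)`), exchange-contribution detection from
  `R2/eta_xy`, and an empirical size→tau_c formula.
- **denaturation** — per-residue two-state urea unfolding fits of
  native-peak intensities, midpoint aggregation, chemical-shift
  perturbations.
- **paramagnetic** — soluble-probe surface accessibility: autoscaled
  volume pairs, attenuations `A_i`, hot-spot classification, regression
  against hydrogen-bond freedom.
- **traj_analysis** — trajectory observables: superposed RMSF,
  hydrogen-bond percentage lifetimes (3.5 A / 75 deg criteria), hydration
  density grids with first-shell/bulk normalization and site detection,
  probe-sphere atom depth indexes.
- **synthetic_data** — seeded generators for every input type with
  machine-readable truth tables (first-class, tested code).
- **peakio / report / cli** — data model, TSV/Sparky/PDB I/O, cross-
  experiment dossiers, structure annotation, `ribodyn` command line.

## Command line

```sh
ribodyn simulate hx --seed 17 --out sim/          # ground-truthed inputs
ribodyn hx --series sim/hx_series.tsv --sequence sim/sequence.fasta \
           --ph 5.65 --temp 300 --out hx.tsv
ribodyn relax --table rates.tsv --field 500.13 --fit modelfree --out mf.tsv
ribodyn denat --series urea.tsv --out denat.tsv
ribodyn para --dia dia.tsv --para para.tsv --threshold 1.7 --out ai.tsv
ribodyn traj --top ref.pdb --traj traj.pdb --rmsf --hbonds --mdhs --out out/
ribodyn report --hx hx.tsv --structure ref.pdb --out anno
```

Every output embeds the tool version and a hash of the effective
configuration; identical configurations reproduce identical files.

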