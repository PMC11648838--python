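# p20kit

Flat-histogram Monte-Carlo sampling of a four-bead coarse-grained (CG)
peptide model, inverse coarse-graining (backmapping) of CG snapshots to
all-atom structures, and the statistics used to calibrate the model's
dimensionless interaction energies against atomistic MD energies.

## What it does

* **`p20kit.prime20_model`** — the CG representation: NH / CA / CO backbone
  beads plus one sidechain center-of-mass bead per residue, in a periodic
  cubic box. Pseudo-bond length constraints with fractional tolerance,
  hard-sphere excluded volume, and square-well attractive interactions.
  The dimensionless energy is `E = -w_bb * N_backbone - w_sc * N_sidechain`
  (defaults 1.0 and 0.08) with saturated (one bond per donor/acceptor)
  greedy contact matching. All numeric parameters live in
  `InteractionParams` and can be overridden via a YAML parameter file.
* **`p20kit.samc_sampler`** — stochastic-approximation flat-histogram
  sampling of the density of states over the exact discrete interaction
  levels `(N_backbone, N_sidechain)`. Acceptance
  `min(1, exp(log_g[cur] - log_g[new]))`, log-DOS update by the decaying
  factor `gamma_t = min(gamma0, t0/t)`, termination at `gamma_t <
  gamma_min` (default `1e-7`). Four move types: single-bead displacement
  (max 0.02 A), phi/psi pivot, whole-chain rotation and translation.
  Fixed-DOS production runs collect snapshots stratified by level.
  `histogram_diagnostics` provides the binned energy histogram, a running
  average, its Fourier power spectrum, and the fractional-part (sidechain)
  projection computed from integer counts.
* **`p20kit.backmapper`** — rebuilds all-atom peptides from CG snapshots:
  backbone N/CA/C from the beads, carbonyl O and amide H constructed in the
  planar trans peptide geometry, rigid equilibrium glutamine sidechain
  templates pinned by mass-weighted COM and the CA->COM axis (free torsion
  resolved by minimum-clash sampling over K=36 candidates), charged termini
  (NH3+ / COO-). Clash detection against fractional van-der-Waals cutoffs;
  PDB v3.3 / GRO output via biotite.
* **`p20kit.calibration_stats`** — energy-trace statistics: effective
  sample count `N = floor(T / tau)` with `tau` a hydrogen-bond lifetime,
  SEM `sigma / sqrt(N)`, running averages, random half-subset consistency
  checks, OLS calibration of mean atomistic energy against CG energy
  (global and per-backbone-count series), hydrogen-bond balance arithmetic,
  and a seeded AR(1) generator that stands in for MD energy output.
* **`p20kit.cli_config`** — validated YAML run configuration (unknown keys
  rejected), deterministic per-stage seed derivation from one global seed,
  text file formats for DOS estimates and snapshot sets, run manifests,
  and the CLI.

## CLI

One executable, `p20kit`, with subcommands forming the pipeline:

```sh
p20kit samc --config run.yaml --out run.dos          # estimate the DOS
p20kit produce --config run.yaml --dos run.dos --steps 100000 --out run.snap
p20kit backmap --snapshots run.snap --index 0 --out conf.pdb
p20kit clashes --snapshots run.snap --index 0 --out clashes.tsv
p20kit make-trace --mean -226130 --stdev 620 --tau 10 --out md.xvg
p20kit trace-stats --trace md.xvg --tau 10
p20kit calibrate --table calibration.tsv             # OLS slope/intercept
p20kit calibrate --table calibration.tsv --per-backbone
```

All subcommands take `--config` (YAML, merged over documented defaults),
`--seed`, and `--verbose`; logs go to stderr, data to files. An empty config
file reproduces the documented defaults (26-residue polyglutamine dimer,
L = 150 A box, max displacement 0.02 A, `gamma_min = 1e-7`).

Energy traces are two-column whitespace text (time ps, energy kJ/mol) with
`#`/`@` comment lines (xvg dialect). Calibration tables are TSV with columns
`e_p20  e_aa  sem  n_backbone  n_sidechain`.

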