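# grnmaps

Simulation toolkit for studying how the **genotype-phenotype (GP)**,
**environment-phenotype (EP)** and **parental-phenotype (PP)** maps of gene
regulatory network (GRN) developmental models covary, and how selecting on
one map drags the others along.

The package provides:

- **`grnmaps.ensemble`** — random GRN genomes and environments
  (network size `N_g ~ U{3..24}`, per-network connectivity `~ U(0,1)`,
  interaction weights `N(0,1)` on the active topology, environmental inputs
  `Exp(1)` clipped to 1, multilinear trait coefficients `U(-1,1)`, diffusion
  rates `U(0,1)`), with seeded reproducibility and an HDF5+JSON+CSV archive.
- **`grnmaps.development`** — Euler integration of the three developmental
  models (well-mixed basic GRN; GRN + multilinear trait readout; 1-D
  reaction-diffusion lattice with zero-flux boundaries), saturating
  Michaelis-Menten production with ramp rectification, decay `mu = 0.1`,
  optional Gaussian noise, a temporal-stability viability criterion, and an
  independent RK45 reference integrator. Hot loops are numba-compiled.
- **`grnmaps.maps`** — GP/EP/PP map construction by systematic perturbation
  of a single GRN element over a 0..1 grid (0.1 steps), general phenotype
  distribution (GPD) sampling, and frozen-context handling for collapsed
  inputs.
- **`grnmaps.metrics`** — map statistics: OLS slopes, the
  `sgn(S)·ln(1+|S|)` slope transform, angular sector classification
  (correlated / anticorrelated / uncorrelated / insensitive), paired
  Euclidean distance, residual-sum map complexity on unit-rescaled traits,
  Pearson correlation, and three multi-trait comparison methods.
- **`grnmaps.evolution`** — mutation-selection-drift evolution of haploid
  populations (fitness-proportional reproduction, non-overlapping
  generations) toward a target map slope, with slope-based
  (`W = exp(-|S - S_T|)`) or Euclidean (`W = exp(-ED)`) fitness, selective
  grain schedules (inputs per generation), target shifting, and post-hoc
  probing of non-selected maps.
- **`grnmaps.controls`** — topology/input randomization controls and the
  random-polynomial complexity null model.
- **`grnmaps.experiments` / `grnmaps.cli`** — end-to-end experiment drivers
  with CSV/JSON outputs.

## Test

```bash
python -m pytest tests/ -q
```

`tests/test_acceptance.py` re-derives the headline statistics at reduced
scale; the remaining files unit- and property-test each module.

## CLI

```bash
# random-ensemble map correlations (slopes, sectors, complexity, ED, GPD)
grnmaps correlations --seed 1 --outdir results/corr --config examples/desk.yaml

# evolve one selected map, then probe the non-selected maps
grnmaps evolve --seed 1 --outdir results/evo --map GP --grain 10 --replicates 5

# selective-grain sweep with Euclidean-distance fitness
grnmaps grain --seed 1 --outdir results/grain --grain-grid 0.25,1,10

# randomization controls + polynomial complexity null
grnmaps controls --seed 1 --outdir results/ctl

# multi-trait (N_t > 2) comparisons
grnmaps multitrait --seed 1 --outdir results/multi --n-traits 4
```

Config files are YAML with `ensemble:`, `development:`, `evolution:` and
`experiment:` sections whose keys mirror the dataclasses
(`EnsembleConfig`, `DevelopmentParams`, `EvolutionConfig`,
`ExperimentSpec`). All model constants default to the reference values
(`dt=1e-3`, `mu=0.1`, `km=1.0`, `noise_sd=1e-2`, `stability_tol=1e-2`,
`n_cells=16`, mutation rate `0.04`, sd `0.01`, `p=64`).

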