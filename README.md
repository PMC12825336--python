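# dexdrop

Water-in-water droplet formation by **dehydration-driven phase separation**
in microfluidic channels: a phase-field simulation of the process, the
phase-diagram and dehydration-kinetics reasoning that predicts when demixing
starts, and a droplet-morphometrics pipeline for quantifying the resulting
populations.

## The problem

A homogeneous aqueous mixture of PEG and dextran (an aqueous two-phase
system, ATPS) is loaded into a narrow channel whose elastomer walls slowly
absorb water. As the polymers concentrate, the composition crosses the
binodal of the PEG/DEX phase diagram and the solution demixes *in situ* into
a single file of uniform, cell-sized dextran-rich droplets inside a PEG-rich
continuum — no shear flow, no surfactants, no flow control. This package is
for researchers in ATPS/LLPS microfluidics and protocell engineering who
want a tested, reproducible implementation of the model and the measurement
pipeline behind that phenomenon.

## What is implemented

- **`dexdrop.thermo`** — regular-solution free energy
  f(η) = RT[η ln η + (1−η) ln(1−η)] + L η(1−η), chemical potential
  μ = RT ln(η/(1−η)) + L(1−2η) − α∇²η, the dehydration ramp
  L(t) = L0 + a(1 − 10^(−bt)), an empirical PEG/DEX binodal
  c_dex = A exp(B√c_peg − C c_peg³) with classification, dilution rays and
  binodal-crossing factors.
- **`dexdrop.solver`** — conserved Cahn–Hilliard dynamics
  ∂η/∂t = ∇·(Mc∇μ), Mc = D0/RT, on a periodic-x / solid-wall-z channel grid,
  with PEG-philic wall relaxation that conserves each column's mass exactly,
  automatic explicit-stability sub-stepping, and the Δt = (step − 800 s)
  observation clock.
- **`dexdrop.dehydration`** — diffusion-limited water-loss laws
  φ(t) ∝ t/width², onset-time prediction and least-squares calibration
  against observed (width, concentration, onset) conditions.
- **`dexdrop.morphometrics`** — droplet segmentation (8-connected
  components, periodic-seam merging), equivalent-circle diameters, mean /
  SD / CV statistics, satellite filtering, width–diameter regression,
  throughput extrapolation and encapsulation-efficiency counting.
- **`dexdrop.synthetic`** — seeded generators for ground-truthed
  fluorescence-like channel images, Poisson particle placements and
  tanh-profile field fixtures.
- **`dexdrop.config` / `dexdrop.cli`** — YAML/TOML-configured pipeline
  (`simulate`, `analyze`, `synth`, `dehydration`, `pipeline` subcommands)
  writing TIFF/CSV/JSON artifacts plus a checksummed manifest.

See `docs/methods.md` for the model assumptions, parameter table, numerical
choices and known limitations.

## Worked example

```python
import numpy as np
from dexdrop import (
    BinodalModel, Composition, GridSpec, InteractionSchedule, SolverConfig,
    ThermoParams, classify_composition, run_simulation, segment_droplets,
    size_statistics, throughput_estimate,
)

m = BinodalModel()
print(classify_composition(Composition(4, 4), m).label)   # homogeneous
print(classify_composition(Composition(5, 5), m).label)   # two_phase

grid = GridSpec()                  # 256 x 20 cells, dx = 1 µm
cfg = SolverConfig(seed=1)         # study parameters, 2600 steps of 1 s
traj = run_simulation(grid, cfg, InteractionSchedule(ThermoParams()))
eta = traj.snapshot_at(2600).eta   # observation time Δt = 30 min
ds = segment_droplets(eta, 0.5, grid_scale=grid.dx, periodic_x=True)
stats = size_statistics(ds, exclude_boundary=False)
print(f"droplets: {stats.n}, mean diameter {stats.mean:.1f} um, "
      f"max {ds.diameters().max():.1f} um, CV {stats.cv:.1f}%")
print(throughput_estimate(stats.linear_density, channels_per_cm=100))
```

prints (about 40 s for the simulation):

```
homogeneous
two_phase
droplets: 24, mean diameter 9.2 um, max 15.6 um, CV 44.7%
{'droplets_per_cm_channel': 937.5, 'droplets_per_cm_width': 93750.0}
```

A 4%:4% mixture starts homogeneous and is driven across the binodal by the
interaction ramp; after 30 min of simulated dehydration the 256 µm channel
segment holds 24 dextran-rich droplets, all narrower than the 20 µm channel
(confinement caps droplet growth). The high CV reflects the satellite
population still coarsening at that time point — `filter_satellites` isolates
the main mode. The throughput figures extrapolate the measured linear
density to one centimetre of channel and to 100 parallel channels.

The same pipeline from the shell:

```sh
dexdrop simulate --seed 1 --outdir out/          # TIFF + mass ledger + stats
dexdrop synth --seed 2 --outdir out_synth/       # ground-truthed image
dexdrop dehydration --outdir out_dehydr/         # calibrated timing model
```

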