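# netspread

Stochastic population spread on geometrically embedded habitat networks, and
its prediction by the weighted algebraic connectivity of the
dispersal-probability graph.

## The problem

When a population expands into a network of habitat patches connected by
movement corridors, how long does it take to occupy every patch — and which
arrangement of corridors makes spread fastest?  The answer depends on two
things jointly: the *configuration* of the habitat network and the species'
*dispersal kernel*, the probability of crossing a corridor as a function of
its length.  A network that accelerates spread for a species that moves far
can impede spread for a species whose dispersal decays quickly with
distance.  `netspread` is built for spatial ecologists who want to simulate
that interaction and quantify it with spectral graph metrics.

The model system is a springtail-style microarthropod metapopulation on
10-node ring arenas: nodes sit on a fixed ring 15 mm apart, a lattice links
each node to its four nearest ring neighbours (15 mm and 90 mm tubes), and
partially (20%) or fully (100%) rewired variants trade that regular
structure for random structure while conserving the 20 links.  Because node
positions are fixed, rewiring changes corridor lengths (15–190 mm).

## Model and metric

Dispersal follows a negative-exponential kernel: the per-day probability
that an individual crosses the corridor between patches *j* and *k* is

    D(j,k) = a · exp(b · W(j,k)),

with `a` the crossing probability at zero distance, `b ≤ 0` the per-mm
decay (fitted value −0.043/mm), and `W(j,k)` the corridor length in mm.  A
distance-independent control model gives every corridor the kernel's
average probability over 15–190 mm.  On top of this sits a stochastic
stage-structured individual-based model (four size classes, adult-only
reproduction, recruitment ceiling, daily reproduce → disperse → die cycle;
juveniles ≤ 7 d old never disperse).  Spread is measured as **time to full
network occupancy**: the first day every node simultaneously holds ≥ 1
individual.

The predictor is the **algebraic connectivity** λ₂ — the second-smallest
eigenvalue of the Laplacian `L = diag(Σₖ D(j,k)) − D` of the
dispersal-probability network.  λ₂ is zero iff the graph is disconnected,
scales linearly under uniform reweighting (so distance-independent kernels
can never reorder networks), and reorders networks as `b` changes when
dispersal is distance-dependent — the rank-reversal at the heart of the
analysis.

## Worked example

```python
from netspread import (DemographicParams, DispersalKernel,
                       generate_topology_set, run_occupancy_experiment,
                       speedup_ratios)

nets = generate_topology_set(seed=1)          # 1 lattice + 8 partial + 8 random
kernel = DispersalKernel(a=0.1, b=-0.0430)    # fitted negative-exponential kernel
tab = run_occupancy_experiment(nets, DemographicParams(), kernel,
                               replicates=50, duration=200, seed=7)
r = speedup_ratios(tab, seed=7)
print(r.mean_by_config)
print(round(r.random_vs_lattice, 2), round(r.random_vs_partial, 2))
```

prints

```
{'lattice': 19.88, 'partial': 25.4375, 'random': 54.4825}
2.74 2.14
```

i.e. with this kernel the lattice fills in ~20 days on average, partially
rewired networks in ~25, and random networks in ~54 — 2.7× and 2.1× slower
than lattice and partial respectively, because rewired corridors are long
and rarely crossed when dispersal decays at 0.043/mm.  Across the 17
topologies the mean occupancy time falls with λ₂ (Spearman ρ = −0.83).

The same analyses are packaged as numbered drivers:

```bash
python analysis/01_generate_networks.py    # the 17 topologies + geometry stats
python analysis/02_connectivity_metrics.py # λ₂, diameters, rank flips across b
python analysis/03_spread_simulations.py   # headline occupancy experiment
python analysis/04_kernel_sweep.py         # occupancy vs b, both dispersal modes
python analysis/05_kernel_recovery.py      # kernel refitting from synthetic trials
```

each writing its tables under `results/`.  A `netspread` command-line
interface (`generate-networks`, `simulate`, `connectivity`, `sweep`,
`analyze`, `synth`, `run`) exposes the same pipeline over YAML/JSON run
configs.

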