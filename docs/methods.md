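# Methods

## Habitat networks

Networks have `n = 10` nodes fixed on a ring (15 mm between ring
neighbours) and `L = 20` links.  Corridor length is a function of the ring
step `k = min(|i−j|, n−|i−j|)` alone, via the step-length table; planar
coordinates are kept only for plotting and serialisation.  The lattice is
the circulant graph with links at steps 1 and 2 (degree 4 everywhere; mean
link length (10·15 + 10·90)/20 = 52.5 mm).

**Rewiring.**  Each link is independently selected with probability equal
to the rewiring fraction (0.2 for "partial", 1.0 for "random").  A selected
link keeps one uniformly chosen endpoint and reattaches the other to a
uniformly chosen node; draws producing a self-loop, a duplicate of an
existing link, or the original pair are resampled, and a draw that
disconnects the network discards the whole network and regenerates it.
Node and link counts are conserved exactly; the default topology set is 1
lattice + 8 partial + 8 random networks, all pairwise distinct as labelled
edge sets (a stricter and cheaper notion than graph isomorphism).

**Step-length calibration.**  Only three corridor lengths are physically
anchored: step 1 = 15 mm, step 2 = 90 mm, and the maximum 190 mm, which we
assign to the antipodal step 5.  Steps 3 and 4 are calibrated, not
measured.  Because duplicate rejection forbids a rewired link from landing
on a short pair that is still occupied, rewired links are strongly biased
toward long ring steps; the realized step frequencies of the generator
(Monte-Carlo, 5000 networks) are ≈ (.405, .407, .075, .075, .038) for
partial and ≈ (.130, .141, .292, .290, .147) for random networks.  We chose
step lengths 3 and 4 (100 mm and 102 mm) so that the expected mean link
length of *partial* networks under these frequencies is 65 mm, the
published figure for arenas of this design.  Under the same table, random
networks average ≈ 101 mm per link, below the published 120 mm; no
monotone table can reproduce both figures with more than ~1 SE of margin
under duplicate-avoiding rewiring, because matching 120 mm for random
networks forces partial networks above 68 mm.  We prioritise the partial
figure (the directly calibrated quantity) and treat the random-network
mean as a self-consistency check of the calibration rather than an
independent datum.  The table is user-configurable for other geometries.

## Dispersal kernel

Per-day crossing probability `D = a·exp(b·W)` with `a ∈ [0,1]` (default
0.1/day — a placeholder: the zero-distance probability is not published for
this system, and all analyses are presented as functions of `b` at fixed
`a`) and `b ≤ 0` per mm (fitted value −0.043 ± 0.007).  The
distance-independent control assigns every link the kernel's uniform
average over [15, 190] mm, computed in closed form
`a·e^{b·lo}·expm1(b·(hi−lo))/(b·(hi−lo))`; `expm1` keeps the removable
singularity at b = 0 stable, and b = 0 returns `a` exactly.  We average the
kernel over the continuous length range rather than over the realized link
set: the former is a property of the landscape, the latter of a particular
network draw (both are one line apart; the continuous form is the
default).

`fit_kernel` estimates (a, b) by nonlinear least squares on success
proportions (scipy `curve_fit`, log-linear starting values, `a` bounded to
[0, 1]) and reports a t-based 95% interval for b.  At the synthetic assay
design used in the recovery analysis (five distances 15–190 mm, 500
binomial trials each) the estimator is unbiased to within Monte-Carlo
error; single-batch estimates have a between-batch SD of ≈ 0.016, so
individual fits are informative about the order of magnitude of b, not its
third decimal.

## Population model

Stochastic individual-based model in daily steps; within a day the order
is reproduce → disperse → die.  Defaults (all configurable):

| parameter | default | units | meaning |
|---|---|---|---|
| `n_stages` | 4 | — | size classes; class 4 = adult |
| `stage_advance_prob` | 0.1 | /day | survivor advances one class |
| `repro_prob` | 0.15 | /day | adult reproduces |
| `clutch_size_mean` | 5 | offspring | Poisson clutch |
| `mortality_prob` | 0.02 | /day | per stage (scalar or per-stage) |
| `density_ceiling` | 300 | individuals/node | recruitment cap (`None` disables) |
| `juvenile_age_threshold` | 7 | days | age at or below which dispersal is blocked |

The life-history rates of the original laboratory population are not
published alongside the study design; these defaults are chosen so that a
seeded node saturates within a few weeks and are flagged as the package's
own calibration — occupancy-time *ratios* between configurations are
sensitive to them (see Limitations).  Density dependence acts on
recruitment only (offspring are discarded once a node reaches the
ceiling), the simplest mechanism that produces saturating node
trajectories.

Runs start with 200 individuals in a single source node, stages drawn
uniformly from the four classes, and initial age set to stage × 7 days so
that all but the smallest class can disperse immediately.  Dispersal: each
individual older than 7 days visits its node's neighbours in a fresh
uniformly random order and moves to the first neighbour whose uniform draw
falls at or below `D(j,k)` — at most one move per individual per day; age
and stage are unchanged by the move, and the total head count is conserved
exactly (asserted in tests).  Mortality is a per-stage Bernoulli;
survivors age one day and advance a stage with the advance probability,
never past the adult class.

Time to full network occupancy is the first day on which *every* node
simultaneously holds at least one individual (a colonized node that dies
out does not count until re-occupied).  Runs that never reach full
occupancy within the 200-day horizon are censored; summary means enter
censored replicates at the horizon and report the censored fraction, and
ratios are additionally available on the uncensored subset.  Replicates
draw independent seeds from a single root `SeedSequence`, so every result
is exactly reproducible from one integer; `stop_when_occupied=True`
truncates the counts table at the occupancy day (used by sweeps), while
the default records counts for every day 0..duration.

## Connectivity metrics

The dispersal-probability graph weights each link by `D` at its length.
λ₂ is the second-smallest eigenvalue of the unnormalized combinatorial
Laplacian, computed by dense symmetric eigendecomposition
(`scipy.linalg.eigvalsh`; cross-checked in tests against networkx's
independent solver and the circulant closed form
`4 − 2cos(π/5) − 2cos(2π/5)`).  Eigenvalues within 1e−9 of zero are
treated as zero; network ranking uses dense ranks so ties share a rank.
Diameters are reported both as link counts and as mm-weighted shortest
paths.  Because λ₂ is 1-homogeneous in the weights, a distance-independent
kernel rescales the whole spectrum and can never change the λ₂ ranking;
with distance-dependent weights 46 of the 136 network pairs in the default
topology set change rank across b ∈ [−0.1, −0.001].

## Synthetic experiment emulator

Generates data with the structure of the 182-day laboratory study so every
analysis stage can be exercised without the original dataset: independent
two-state ("food added"/"no food") Markov food series per node (default
transitions 0.3/0.3 — placeholders, not biological estimates; the food
series does not feed back into the population model, whose vital rates
have no food term — an optional hook multiplying the reproduction
probability by a food factor exists but is off by default), observation
schedules with i.i.d. gaps of 1–2 (occasionally 5) days, binomial thinning
of counts with detection probability 0.95, and binomial corridor-crossing
trials for kernel fitting.  Thinning plus schedule gaps can only delay
apparent colonization, and observed occupancy days preserve the ranking of
true occupancy days (rank correlation > 0.9 at the default design) — so
analyses run on observed-style data are late-biased but order-faithful.
What passing these tests does *not* show: robustness to the real
experiment's spatially structured detection errors, double counting, or
food-driven demography.

## Statistical analyses

Speed-up ratios are quotients of mean occupancy days between
configurations with percentile bootstrap CIs over replicates (1000
resamples).  The occupancy–connectivity regression is OLS of per-topology
mean occupancy day on λ₂ (statsmodels), reported with R² alongside the R²
of the one-way configuration ANOVA on the same per-topology means.  Under
the default conditions λ₂'s linear R² (0.41) is *below* the
three-level configuration ANOVA's (0.61) while its rank correlation is
strong (ρ = −0.83): with only 17 topologies and a 25-fold λ₂ range the
λ₂–occupancy relation is monotone but visibly nonlinear, so a single
linear slope understates it.

## Problem sizes and reproducibility

Headline experiment: 17 topologies × 50 replicates × 200-day horizon
(≈ 15 s single-core).  Kernel sweeps: 20 replicates per (topology, b,
mode) cell across five exponents.  Kernel recovery: 200 synthetic batches.
These sizes give Monte-Carlo SEs well below the effects of interest (e.g.
ratio CIs of ± 0.1–0.2) and are the defaults of the analysis drivers.

## Known limitations

- Occupancy-time ratios between configurations depend on the unpublished
  life-history rates and kernel intercept; with this package's defaults the
  fitted-kernel ratios are ≈ 2.7 (random/lattice) and ≈ 2.1
  (random/partial) — the qualitative ordering is robust, the magnitudes
  are calibration-dependent.
- Under the default calibration the fastest-configuration flip in the
  distance-dependent model sits very close to a flat kernel (|b| ≲ 0.001
  /mm): random networks overtake the lattice only once the long-corridor
  penalty `e^{−|b|·175}` shrinks below the lattice's ≈ 15% topological
  disadvantage, and near that point the three configurations differ by
  fractions of a day.  Lattice and partially rewired networks are
  statistically indistinguishable in the distance-independent model except
  under strong decay.
- The random-network mean link length (≈ 101 mm) undershoots the published
  120 mm, a structural consequence of duplicate-avoiding rewiring (see the
  calibration note above).
- Corridors are traversed instantaneously between days; there is no
  within-corridor mortality, no sex structure, and no food-dependent vital
  rates in the population model.
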