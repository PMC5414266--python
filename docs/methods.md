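# Methods

## Model

Organisms are points in a continuous, bounded phenotype space
`[0, L] × [0, L]` (default `L = 45` arbitrary units). The model is neutral:
every organism produces the same number of offspring `f` and faces the same
death probability `δ`. A run starts from `N0 = 300` organisms placed
independently and uniformly (chosen to shorten the transient; the dynamics
are Markovian in the population state, so the initial condition does not
affect the phase behaviour) and proceeds for up to `G` non-overlapping
generations or until extinction, which is absorbing.

Each generation:

1. **Mate assignment.** Assortative mating: each organism's mate is its
   Euclidean nearest neighbour, its alternate mate the second-nearest;
   pairings need not be mutual. Random mating: mate and alternate are drawn
   uniformly without replacement from the rest of the population. Asexual
   fission has no mates, but nearest/second-nearest "mates" are still
   assigned for cluster accounting (phenotypic similarity). With a single
   organism no mate exists under the sexual schemes and the lineage ends —
   the minimal rule consistent with mating requiring a distinct partner.
2. **Reproduction and dispersal.** Acting once as the reference parent,
   each organism contributes `f` offspring placed uniformly in the
   axis-aligned bounding box of the two parents expanded by the mutability
   `μ` on every side; this box degenerates to the asexual `2μ × 2μ` square
   when the parents coincide, which is exactly the asexual dispersal rule.
   Offspring may land outside the landscape; they are removed at stage 5,
   not clipped. All parents are then removed.
3. **Competition.** Conflicting pairs (distance strictly `< κ`, default
   `κ = 0.25`) are resolved by visiting the pairs in RNG-shuffled order and
   removing one member of each still-intact pair by fair coin flip. Since a
   removal never creates a new conflict, one pass reaches the fixed point:
   survivors are never closer than `κ`. For chains of three or more mutually
   conflicting organisms the surviving *set* depends on the visiting order;
   the shuffled-sequential rule is this package's documented choice, and the
   tests check the outcome distribution only against the enumeration of all
   sequential resolutions. The choice matters quantitatively: it sets how
   many deaths a given density produces, and therefore the equilibrium
   packing (see "Known limitations").
4. **Stochastic death.** Every organism draws uniform on [0, 1) and dies
   when the draw is ≤ `δ`.
5. **Boundary removal.** Organisms outside the closed square `[0, L]²` are
   removed.

Order parameters are recorded *after* all three death stages: population
size `N`, the number of mate clusters, the Clark–Evans index `R`, the
filling factor `η`, and whether any mate cluster spans the landscape. `R`
and `η` are reported as NaN (undefined, not zero) when `N < 2`.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `L` | landscape side | 45 | trait units |
| `N0` | initial population | 300 | organisms |
| `μ` | mutability (dispersal half-width) | 0.30 | trait units |
| `δ` | individual death probability | — (control parameter) | probability |
| `κ` | competition limit / disc radius | 0.25 | trait units |
| `f` | offspring per organism | 2 | count |
| `G` | generations | 2000 | — |

`δ` is the primary control parameter (classically swept over [0.01, 0.50]
in steps of 0.01 at `f = 2`); the fitness sweep instead holds `δ = 0.01`
and varies `f` over the integers for 250 generations. `κ` is exposed but
held constant throughout.

## Clusters and percolation

An organism, its mate and its alternate form a cluster seed; seeds sharing
an organism merge iteratively into reproductively isolated clusters. That
fixed point equals the connected components of the graph with edges
(i, mate_i) and (i, alternate_i), which is how clusters are computed (the
literal iterative merge is kept as a test oracle). A cluster **spans** when
its extent reaches within a margin of both opposite boundaries along either
axis; the landscape offers no natural margin other than the competition
limit, so the default margin is `κ` (the choice is a parameter). Disc
clusters connect organisms whose distance is `< 2κ` (overlapping radius-κ
discs); disc spanning uses the same rule with margin `κ`. Bond (mate)
clusters can span while disc clusters do not.

The continuum-percolation threshold estimator is pure geometry, independent
of the evolutionary model: radius-`r` discs are dropped as a Poisson process
of intensity `η/(πr²)` in a `32r` box, a replicate spans when a connected
chain of overlapping discs joins discs touching the left and right edges,
and `η_c` is the 50% crossing of the spanning probability (logistic fit,
linear-interpolation fallback; percentile bootstrap over the per-η binomial
counts for the CI). At this box size the estimator lands within a few
percent of the infinite-volume threshold; the residual finite-size bias is
included in the quoted CI width, not corrected.

## Clark–Evans index

`R = r_A / r_E` with `r_E = 1/(2√ρ)`, `ρ = N/area`, using the original 1954
estimator **without edge correction**: boundary organisms lack neighbours
beyond the border, which biases `r_A` slightly upward at moderate `N`.
Modern corrected estimators would shift `R`; the uncorrected form is kept
deliberately so simulator values are comparable with the classical limits
(1 for Poisson patterns, 2.1491 for hexagonal packing), which the lattice
and Poisson fixtures verify to ±0.001 and ±0.02 respectively. The area used
for simulator snapshots is always `L²`; fixtures pass their analytic areas.

## Critical-point extraction

`δ_c` is the largest swept `δ` at which the population survives the full
run, where survival at a grid value means **any** of the replicates
completes `G` generations with `N > 0` — robust at small replicate counts,
and consistent with survival occurring just below the critical point.
`δ_R` is the linear interpolation of the across-replicate mean
final-generation `R` to its crossing of 1 (None when no two consecutive
defined means bracket 1). Order parameters enter these estimates at the
final generation; full trajectories are stored, so time-averaged variants
can be computed without re-simulation.

Replicate seeds are 31-bit integers derived from
`(master_seed, value_index, replicate)` via `numpy.random.SeedSequence`
spawn keys; a sweep is exactly reproducible from its master seed.

## Verification scale

The package's standard verification experiments (the test suite) run
reduced problem sizes: `G = 500`, 3 replicates, grid step 0.01, with each
sweep restricted to a window bracketing its critical region —
assortative μ = 0.30 on [0.15, 0.32], μ = 0.60 on [0.30, 0.46],
μ = 0.90 on [0.35, 0.50], asexual μ = 0.30 on [0.18, 0.34]. Windows are
wide enough that every estimate lies strictly inside them (the estimators
raise if survival touches a window edge), and each window also contains the
`R = 1` crossing. Shortening `G` from 2000 to 500 biases `δ_c` upward by
roughly one grid step, since marginal populations that would die later
still count as survivors; estimates here come out 0.01–0.02 above the
full-scale values. The fitness sweep uses `L = 20` (η is intensive, and
equilibrium values at `L = 20` and `L = 45` agree), 5 replicates, 250
generations. The continuum-percolation estimate uses a 32-radius box with
200–300 replicates per grid point. Full-scale runs (`G = 2000`, the
complete δ grid, 20-replicate fitness sweeps) are available through the
same interfaces and the CLI.

## What the generator does and does not emulate

The simulator *is* the study system — there is no external data. What the
model omits relative to real populations: genetics (reproductive isolation
is purely phenotypic and can be undone next generation when descendant
clusters re-approach), selection (no fitness differences by construction),
environmental structure, and geographic space (the plane is trait space, so
"dispersal" is phenotypic innovation, not migration). Passing tests
therefore validate the dynamical rules and their statistical signatures,
not any claim about a particular biological system.

## Numerical choices

* Nearest-neighbour queries use a KD-tree; exact distance ties (measure
  zero in continuous space, but present on lattices and crafted inputs)
  are broken uniformly at random. Ties beyond the 8 nearest candidates are
  not re-sampled.
* Conflict pairs at exactly `κ` are *not* in conflict (strict inequality);
  boundary membership is the closed interval.
* Competition resolution consumes its shuffle and its coin flips from the
  run's single generator in a fixed order, so trajectories are bit-for-bit
  reproducible by seed on one platform.
* Extinct sweeps report `final_N = 0` and `η = 0`; `R` is undefined and
  excluded from across-replicate means.
* The logistic fit for `η_c` falls back to linear interpolation when the
  fit fails or leaves the grid.

## Known limitations

* The equilibrium density at fixed `f` — hence the filling factor `η` —
  depends on the competition victim-resolution order (step 3 above).
  Under the shuffled-sequential rule the mean equilibrium η at `f = 3`,
  `δ = 0.01` measures ≈ 1.05, so the site-percolation threshold
  `η_c ≈ 1.12` is crossed between `f = 3` and `f = 4`; a minimal-removal
  resolution would reach higher packing at the same `f`. The survival
  critical points `δ_c` are insensitive to this choice.
* No genealogy or lineage tracking, no time-dependent death probability,
  no κ sweeps, and no critical-exponent estimation; the sweep machinery
  stops at locating critical points.
* `δ_c` from 500-generation sweeps carries the upward finite-time bias
  described above; treat sweeping-scale estimates as upper bounds on the
  long-run values.
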