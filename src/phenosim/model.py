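"""Simulation state, one-generation stepping, and full runs.

A generation is non-overlapping: every organism reproduces (per the chosen
scheme), all parents are removed, and the offspring pass through the
ordered death pipeline (competition -> stochastic death -> boundary
removal). Extinction (N = 0) is absorbing. Order parameters — population
size, number of mate clusters, Clark–Evans R, filling factor eta, and
whether any bonded cluster spans the landscape — are recorded for the
population that exists after all three death stages each generation.

All stochastic draws of one run come from a single seeded generator, in a
fixed order per generation: mate assignment (including nearest-neighbour
tie-breaks), offspring dispersal, competition (pair shuffle, then coin
flips), stochastic-death draws. Identical parameters and seed therefore
reproduce a trajectory bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .clustering import build_bond_graph, find_clusters, spanning_clusters
from .metrics import clark_evans_R
from .mortality import apply_boundary, apply_competition, apply_stochastic_death
from .reproduction import (
    MateAssignment,
    assign_mates_assortative,
    assign_mates_random,
    spawn_offspring_asexual,
    spawn_offspring_sexual,
)

SCHEMES = ("assortative", "random", "asexual")


@dataclass(frozen=True)
class SimParams:
    """All control parameters of one simulation.

    Attributes
    ----------
    L : landscape side length, phenotype units.
    N0 : initial population size, placed uniformly at random.
    mu : mutability — half-width of the offspring dispersal region.
    delta : per-organism, per-generation stochastic death probability.
    kappa : competition limit; also the disc radius for percolation metrics.
    f : fitness — offspring produced per organism per generation.
    scheme : "assortative", "random" or "asexual".
    G : maximum number of generations.
    seed : RNG seed (None draws OS entropy; pass an int for reproducibility).
    """

    L: float = 45.0
    N0: int = 300
    mu: float = 0.30
    delta: float = 0.0
    kappa: float = 0.25
    f: int = 2
    scheme: str = "assortative"
    G: int = 2000
    seed: int | None = None

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.N0 < 0:
            raise ValueError("N0 must be non-negative")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if int(self.f) != self.f or self.f < 1:
            raise ValueError("f must be a positive integer")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.G < 0:
            raise ValueError("G must be non-negative")


@dataclass(frozen=True)
class Population:
    """Organism coordinates alive at one generation."""

    coords: np.ndarray  # (N, 2) float, phenotype units
    generation: int = 0

    @property
    def n(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class GenerationRecord:
    """Order parameters of the population existing at one generation.

    ``R`` and ``eta`` are NaN (undefined) when fewer than two organisms
    remain; ``n_clusters`` counts a lone organism as one trivial cluster.
    """

    generation: int
    N: int
    n_clusters: int
    R: float
    eta: float
    spanning: bool


@dataclass(frozen=True)
class Trajectory:
    """Full per-generation record of one simulation run."""

    records: tuple[GenerationRecord, ...]
    extinct: bool
    extinction_generation: int | None
    params: SimParams
    seed_used: int | None

    @property
    def final(self) -> GenerationRecord:
        return self.records[-1]

    @property
    def survived(self) -> bool:
        return not self.extinct

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "N": [r.N for r in self.records],
                "n_clusters": [r.n_clusters for r in self.records],
                "R": [r.R for r in self.records],
                "eta": [r.eta for r in self.records],
                "spanning": [r.spanning for r in self.records],
            }
        )


def init_population(params: SimParams, rng: np.random.Generator) -> Population:
    """N0 organisms placed independently and uniformly on [0, L]^2."""
    coords = rng.random((params.N0, 2)) * params.L
    return Population(coords=coords, generation=0)


def assign_mates(pop: Population, params: SimParams, rng: np.random.Generator) -> MateAssignment | None:
    """Scheme-appropriate mate assignment, or None when fewer than two organisms.

    Under asexual reproduction the "mates" are the nearest and second-nearest
    phenotypic neighbours; they play no role in reproduction but define the
    clusters.
    """
    if pop.n < 2:
        return None
    if params.scheme == "random":
        return assign_mates_random(pop.n, rng)
    return assign_mates_assortative(pop.coords, rng)


def step_generation(
    pop: Population,
    params: SimParams,
    rng: np.random.Generator,
    mates: MateAssignment | None = None,
) -> Population:
    """Advance one generation: reproduce, then compete, die, cull at boundary.

    Parents never persist. Under the sexual schemes a single organism has no
    mate and leaves no offspring, so N = 1 ends the lineage. ``mates`` may
    carry a pre-computed assignment for the current population (e.g. the one
    used to record its clusters); if omitted one is drawn here.
    """
    if pop.n == 0:
        return Population(coords=np.empty((0, 2)), generation=pop.generation + 1)
    if params.scheme == "asexual":
        offspring = spawn_offspring_asexual(pop.coords, params.f, params.mu, rng)
    else:
        if pop.n < 2:
            return Population(coords=np.empty((0, 2)), generation=pop.generation + 1)
        if mates is None:
            mates = assign_mates(pop, params, rng)
        offspring = spawn_offspring_sexual(pop.coords, mates, params.f, params.mu, rng)
    offspring = apply_competition(offspring, params.kappa, rng)
    offspring = apply_stochastic_death(offspring, params.delta, rng)
    offspring = apply_boundary(offspring, params.L)
    return Population(coords=offspring, generation=pop.generation + 1)


def _record(
    pop: Population, mates: MateAssignment | None, params: SimParams
) -> GenerationRecord:
    n = pop.n
    if n == 0:
        return GenerationRecord(pop.generation, 0, 0, math.nan, math.nan, False)
    if n == 1:
        return GenerationRecord(pop.generation, 1, 1, math.nan, math.nan, False)
    partition = find_clusters(build_bond_graph(n, mates))
    spans = spanning_clusters(pop.coords, partition, params.L, margin=params.kappa)
    R = clark_evans_R(pop.coords, params.L * params.L).R
    eta = (n / (params.L * params.L)) * math.pi * params.kappa**2
    return GenerationRecord(pop.generation, n, partition.n_clusters, R, eta, bool(spans))


def run_simulation(params: SimParams) -> Trajectory:
    """Run up to G generations or until the absorbing extinction state.

    Each generation's mate assignment is drawn once, used both to record the
    cluster structure of the existing population and (for the sexual
    schemes) to produce the next generation's offspring.
    """
    rng = np.random.default_rng(params.seed)
    pop = init_population(params, rng)
    mates = assign_mates(pop, params, rng)
    records = [_record(pop, mates, params)]
    extinct = pop.n == 0
    extinction_generation: int | None = 0 if extinct else None
    for g in range(1, params.G + 1):
        if extinct:
            break
        pop = step_generation(pop, params, rng, mates=mates)
        mates = assign_mates(pop, params, rng)
        records.append(_record(pop, mates, params))
        if pop.n == 0:
            extinct = True
            extinction_generation = g
    return Trajectory(
        records=tuple(records),
        extinct=extinct,
        extinction_generation=extinction_generation,
        params=params,
        seed_used=params.seed,
    )


def with_params(params: SimParams, **overrides) -> SimParams:
    """Convenience wrapper around dataclasses.replace for sweeps."""
    return replace(params, **overrides)
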