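"""Mate selection and offspring dispersal.

Three reproduction schemes are supported:

* assortative mating — each organism takes its nearest neighbour in
  phenotype space as its mate and its second-nearest as an alternate mate;
* random mating — mate and alternate are drawn uniformly at random from the
  rest of the population, without replacement;
* asexual fission — no mates; each organism produces offspring around its
  own position.

Offspring are placed uniformly at random inside a dispersal region: the
axis-aligned bounding box of the two parents (or the single parent, for
fission), expanded by the mutability ``mu`` on every side. Mating pairs need
not be mutual — each organism acts once as the reference parent and
contributes ``f`` offspring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

#: Sentinel index meaning "no such partner" (e.g. no alternate mate at N = 2).
NO_MATE = -1


@dataclass(frozen=True)
class MateAssignment:
    """Per-organism mate and alternate-mate indices.

    ``alternate`` entries are :data:`NO_MATE` where no distinct second
    partner exists (N < 3).
    """

    mate: np.ndarray
    alternate: np.ndarray

    def __post_init__(self):
        n = len(self.mate)
        i = np.arange(n)
        if np.any(self.mate == i):
            raise ValueError("an organism cannot mate with itself")
        defined = self.alternate != NO_MATE
        if np.any(self.alternate[defined] == i[defined]):
            raise ValueError("an organism cannot be its own alternate mate")
        if np.any(self.alternate[defined] == self.mate[defined]):
            raise ValueError("mate and alternate must be distinct")

    @property
    def n(self) -> int:
        return len(self.mate)


@dataclass(frozen=True)
class DispersalBox:
    """Axis-aligned offspring placement region, in phenotype units.

    May extend beyond the landscape; out-of-bounds offspring are culled
    later by boundary removal, not clipped here.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= self.xmin)
            & (p[:, 0] <= self.xmax)
            & (p[:, 1] >= self.ymin)
            & (p[:, 1] <= self.ymax)
        )


def _as_coords(x) -> np.ndarray:
    coords = np.asarray(getattr(x, "coords", x), dtype=float)
    if coords.size == 0:
        return coords.reshape(0, 2)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coordinates must be an (N, 2) array")
    return coords


def assign_mates_assortative(pop, rng: np.random.Generator, k_search: int = 8) -> MateAssignment:
    """Nearest-neighbour mate and second-nearest alternate for every organism.

    Distance ties are broken uniformly at random (exact ties have measure
    zero in continuous space but occur on lattice fixtures and crafted
    inputs). Pairings need not be mutual.

    ``k_search`` bounds the neighbour candidates examined per organism; ties
    extending past the ``k_search``-th neighbour are not re-sampled, which is
    irrelevant for generic continuous configurations.
    """
    coords = _as_coords(pop)
    n = len(coords)
    if n < 2:
        raise ValueError("assortative mating requires at least two organisms")
    k = min(n, max(3, k_search)) if n >= 3 else 2
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    # Mask each organism's own entry by index (robust to coincident points).
    dist = np.where(idx == np.arange(n)[:, None], np.inf, dist)
    tiebreak = rng.random(dist.shape)
    order = np.lexsort((tiebreak, dist), axis=1)
    ranked = np.take_along_axis(idx, order, axis=1)
    mate = ranked[:, 0]
    if n >= 3:
        alternate = ranked[:, 1]
    else:
        alternate = np.full(n, NO_MATE)
    return MateAssignment(mate=mate, alternate=alternate)


def assign_mates_random(pop, rng: np.random.Generator) -> MateAssignment:
    """Uniform-random mate and distinct alternate from the rest of the population.

    ``pop`` may be a population, an (N, 2) coordinate array, or an integer
    count — only the count matters here.
    """
    if isinstance(pop, (int, np.integer)):
        n = int(pop)
    else:
        n = len(_as_coords(pop))
    if n < 2:
        raise ValueError("random mating requires at least two organisms")
    i = np.arange(n)
    mate = rng.integers(0, n - 1, size=n)
    mate = mate + (mate >= i)
    if n >= 3:
        lo = np.minimum(i, mate)
        hi = np.maximum(i, mate)
        alternate = rng.integers(0, n - 2, size=n)
        # Shift past the two excluded indices in ascending order.
        alternate = alternate + (alternate >= lo)
        alternate = alternate + (alternate >= hi)
    else:
        alternate = np.full(n, NO_MATE)
    return MateAssignment(mate=mate, alternate=alternate)


def dispersal_box(p1, p2, mu: float) -> DispersalBox:
    """Bounding box of the two parents expanded by ``mu`` on every side.

    With coincident parents this degenerates to the asexual 2mu x 2mu
    square centred on the parent.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return DispersalBox(
        xmin=min(p1[0], p2[0]) - mu,
        xmax=max(p1[0], p2[0]) + mu,
        ymin=min(p1[1], p2[1]) - mu,
        ymax=max(p1[1], p2[1]) + mu,
    )


def spawn_offspring_sexual(
    pop, mates: MateAssignment, f: int, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Offspring of every (reference, mate) pair, ``f`` per reference organism.

    Each organism acts once as the reference parent; its ``f`` offspring are
    uniform in the dispersal box spanned by itself and its mate. Returns an
    (f*N, 2) array, offspring grouped by reference parent.
    """
    coords = _as_coords(pop)
    n = len(coords)
    p1 = coords
    p2 = coords[mates.mate]
    lo = np.minimum(p1, p2) - mu
    hi = np.maximum(p1, p2) + mu
    u = rng.random((n, f, 2))
    offspring = lo[:, None, :] + u * (hi - lo)[:, None, :]
    return offspring.reshape(-1, 2)


def spawn_offspring_asexual(pop, f: int, mu: float, rng: np.random.Generator) -> np.ndarray:
    """``f`` offspring per parent, uniform in the 2mu x 2mu square centred on it."""
    coords = _as_coords(pop)
    n = len(coords)
    u = rng.random((n, f, 2))
    offspring = (coords - mu)[:, None, :] + u * (2.0 * mu)
    return offspring.reshape(-1, 2)
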