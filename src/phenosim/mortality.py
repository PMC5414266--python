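"""The ordered three-stage death pipeline.

Offspring pass, in this fixed order, through

1. competition — whenever two organisms sit closer than the competition
   limit ``kappa``, one of the two (chosen by fair coin flip) is removed,
   until no pair remains within ``kappa``;
2. stochastic death — every organism independently draws a uniform number
   and dies when the draw is at or below the death probability ``delta``;
3. boundary removal — organisms outside the closed landscape square are
   removed.

The pipeline order matters and is pinned by a regression test: an organism
outside the boundary can still kill a neighbour through competition before
it is itself removed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .reproduction import _as_coords

try:  # optional JIT for the sequential conflict-resolution loop
    from numba import njit

    @njit(cache=False)
    def _resolve(pairs_i, pairs_j, order, kill_first, n):  # pragma: no cover
        alive = np.ones(n, dtype=np.bool_)
        for k in order:
            i = pairs_i[k]
            j = pairs_j[k]
            if alive[i] and alive[j]:
                if kill_first[k]:
                    alive[i] = False
                else:
                    alive[j] = False
        return alive

except ImportError:  # pragma: no cover

    def _resolve(pairs_i, pairs_j, order, kill_first, n):
        alive = np.ones(n, dtype=bool)
        for k in order:
            i = pairs_i[k]
            j = pairs_j[k]
            if alive[i] and alive[j]:
                alive[i if kill_first[k] else j] = False
        return alive


def apply_competition(pop, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Remove one of every pair of organisms closer than ``kappa``.

    Conflicting pairs (strict distance < kappa) are visited in an
    RNG-shuffled order; for each pair whose members are both still alive,
    a fair coin decides which one dies. Because removals never create new
    conflicts, a single shuffled pass reaches the fixed point: survivors
    have all pairwise distances >= kappa. Survivors at exactly ``kappa``
    are legal (discs may touch up to the radial distance).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    coords = _as_coords(pop)
    n = len(coords)
    if n < 2:
        return coords.copy()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(kappa, output_type="ndarray")
    if len(pairs):
        d2 = np.sum((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2, axis=1)
        pairs = pairs[d2 < kappa * kappa]  # query_pairs includes distance == r
    if len(pairs) == 0:
        return coords.copy()
    order = rng.permutation(len(pairs))
    kill_first = rng.random(len(pairs)) < 0.5
    alive = _resolve(
        np.ascontiguousarray(pairs[:, 0], dtype=np.int64),
        np.ascontiguousarray(pairs[:, 1], dtype=np.int64),
        order.astype(np.int64),
        kill_first,
        n,
    )
    return coords[alive]


def apply_stochastic_death(pop, delta: float, rng: np.random.Generator) -> np.ndarray:
    """Independently remove each organism with probability ``delta``.

    Each organism draws uniform on [0, 1); a draw at or below ``delta``
    removes it.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    coords = _as_coords(pop)
    draws = rng.random(len(coords))
    return coords[draws > delta]


def apply_boundary(pop, L: float) -> np.ndarray:
    """Retain exactly the organisms inside the closed square [0, L] x [0, L]."""
    coords = _as_coords(pop)
    if len(coords) == 0:
        return coords.copy()
    inside = (
        (coords[:, 0] >= 0.0)
        & (coords[:, 0] <= L)
        & (coords[:, 1] >= 0.0)
        & (coords[:, 1] <= L)
    )
    return coords[inside]
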