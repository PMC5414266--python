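"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths (KD-trees, sparse
graph components, vectorised resolution) so that agreement is evidence,
not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_neighbours(coords):
    """O(N^2) nearest and second-nearest neighbour indices and distances.

    Returns (nn_idx, nn_dist, snn_idx, snn_dist); ties resolved by lowest
    index (callers comparing against randomised tie-breaking should only
    use instances without ties, or compare distances).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    nn_idx = np.empty(n, dtype=int)
    nn_dist = np.empty(n)
    snn_idx = np.full(n, -1, dtype=int)
    snn_dist = np.full(n, np.inf)
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            d = float(np.hypot(*(coords[i] - coords[j])))
            dists.append((d, j))
        dists.sort()
        nn_dist[i], nn_idx[i] = dists[0]
        if len(dists) > 1:
            snn_dist[i], snn_idx[i] = dists[1]
    return nn_idx, nn_dist, snn_idx, snn_dist


def brute_force_nn_distances(coords):
    return brute_force_neighbours(coords)[1]


def seed_merge_clusters(n, mate, alternate):
    """Literal iterative cluster-seed merging.

    Every organism starts a seed {i, mate[i], alternate[i]}; any two seeds
    sharing an organism are merged, repeatedly, until no merge applies.
    Returns a list of frozensets partitioning range(n).
    """
    seeds = []
    for i in range(n):
        members = {i, int(mate[i])}
        if alternate[i] >= 0:
            members.add(int(alternate[i]))
        seeds.append(set(members))
    changed = True
    while changed:
        changed = False
        out = []
        for seed in seeds:
            for other in out:
                if other & seed:
                    other |= seed
                    changed = True
                    break
            else:
                out.append(set(seed))
        seeds = out
    return [frozenset(s) for s in seeds]


def partition_as_sets(labels):
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == lab).tolist()) for lab in np.unique(labels)}


def min_pairwise_distance(coords):
    coords = np.asarray(coords, dtype=float)
    best = np.inf
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            best = min(best, float(np.hypot(*(coords[i] - coords[j]))))
    return best


def enumerate_competition_outcomes(coords, kappa):
    """All survivor sets reachable by sequential pairwise conflict resolution.

    Explores every order of picking a currently conflicting pair and every
    victim choice. Exponential; only for tiny instances.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)

    def conflicts(alive):
        alive = sorted(alive)
        return [
            (i, j)
            for i, j in itertools.combinations(alive, 2)
            if np.hypot(*(coords[i] - coords[j])) < kappa
        ]

    outcomes = set()
    stack = [frozenset(range(n))]
    seen = set()
    while stack:
        alive = stack.pop()
        if alive in seen:
            continue
        seen.add(alive)
        cons = conflicts(alive)
        if not cons:
            outcomes.add(alive)
            continue
        for i, j in cons:
            stack.append(alive - {i})
            stack.append(alive - {j})
    return outcomes
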