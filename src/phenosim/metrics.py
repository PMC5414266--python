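"""Spatial point-pattern statistics.

Two statistics characterise how organisms fill the morphospace:

* the Clark & Evans nearest-neighbour index R = r_A / r_E, the ratio of the
  observed mean nearest-neighbour distance r_A to the expectation under
  complete spatial randomness, r_E = 1 / (2 sqrt(rho)) with rho = N / area.
  R < 1 marks aggregation, R = 1 randomness, R > 1 uniform dispersion; a
  hexagonally packed population approaches the maximum R = 2.1491;
* the continuum-percolation filling factor eta = rho * a with disc area
  a = pi * kappa^2, and the covered area fraction phi = 1 - exp(-eta).
  Overlapping-disc percolation occurs near eta_c ≈ 1.12 (phi_c ≈ 0.67).

The original (1954) Clark & Evans estimator is used deliberately, without
modern edge corrections — see the methods note.

Also provides deterministic lattice and Poisson point fixtures whose R is
known in closed form, used as analytic oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .reproduction import _as_coords


@dataclass(frozen=True)
class SpatialPatternMetrics:
    """Clark–Evans summary of one point pattern."""

    N: int
    rho: float  # density, points per unit area
    r_A: float  # observed mean nearest-neighbour distance
    r_E: float  # expected NN distance under randomness, 1/(2 sqrt(rho))
    R: float  # r_A / r_E


@dataclass(frozen=True)
class PercolationMetrics:
    """Continuum-percolation occupancy of a point pattern of discs."""

    a: float  # disc area pi * kappa^2
    eta: float  # filling factor rho * a
    phi: float  # covered fraction 1 - exp(-eta)


def nearest_neighbor_distances(pop) -> np.ndarray:
    """Distance from every organism to its closest other organism."""
    coords = _as_coords(pop)
    if len(coords) < 2:
        raise ValueError("nearest-neighbour distances require at least two points")
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    return dist[:, 1]


def clark_evans_R(pop, area: float) -> SpatialPatternMetrics:
    """Clark–Evans index of a point pattern on a region of the given area."""
    coords = _as_coords(pop)
    n = len(coords)
    if n < 2:
        raise ValueError("Clark-Evans index requires at least two points")
    if area <= 0:
        raise ValueError("area must be positive")
    rho = n / area
    r_a = float(np.mean(nearest_neighbor_distances(coords)))
    r_e = 1.0 / (2.0 * math.sqrt(rho))
    return SpatialPatternMetrics(N=n, rho=rho, r_A=r_a, r_E=r_e, R=r_a / r_e)


def filling_factor(N: int, area: float, kappa: float) -> PercolationMetrics:
    """Filling factor and coverage of ``N`` radius-``kappa`` discs on ``area``."""
    if area <= 0:
        raise ValueError("area must be positive")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if N < 0:
        raise ValueError("N must be non-negative")
    a = math.pi * kappa * kappa
    eta = (N / area) * a
    phi = 1.0 - math.exp(-eta)
    return PercolationMetrics(a=a, eta=eta, phi=phi)


def generate_fixture(
    kind: str,
    n: int,
    spacing: float = 1.0,
    box: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reference point sets with analytically known spatial statistics.

    Parameters
    ----------
    kind
        ``"square"`` — square lattice with the given spacing (R = 2 exactly
        with area = n * spacing^2);
        ``"hexagonal"`` — triangular/hexagonal-packing lattice (R = 2.1491
        with area = n * spacing^2 * sqrt(3)/2);
        ``"poisson"`` — homogeneous Poisson field with expected count ``n``
        on a ``box`` x ``box`` square (R ≈ 1 for large n).
    n
        Number of points (exact for lattices, expectation for Poisson).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if kind == "square":
        cols = math.ceil(math.sqrt(n))
        idx = np.arange(n)
        rows, c = np.divmod(idx, cols)
        return np.column_stack([c * spacing, rows * spacing]).astype(float)
    if kind == "hexagonal":
        cols = math.ceil(math.sqrt(n))
        idx = np.arange(n)
        rows, c = np.divmod(idx, cols)
        x = c * spacing + (rows % 2) * (spacing / 2.0)
        y = rows * (spacing * math.sqrt(3.0) / 2.0)
        return np.column_stack([x, y]).astype(float)
    if kind == "poisson":
        if box is None or box <= 0:
            raise ValueError("poisson fixture requires a positive box side")
        if rng is None:
            raise ValueError("poisson fixture requires an rng")
        count = rng.poisson(n)
        return rng.random((count, 2)) * box
    raise ValueError(f"unknown fixture kind: {kind!r}")
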