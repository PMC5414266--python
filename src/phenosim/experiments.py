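"""Sweep experiments and critical-point extraction.

Reproduces the model's figure-level computations:

* death-probability sweeps with replicate statistics, giving the
  non-equilibrium survival/extinction transition in delta;
* extraction of the critical death probability delta_c (the largest swept
  delta at which the population survives the full run) and of delta_R, the
  interpolated delta at which the mean Clark–Evans index crosses 1;
* fitness sweeps of the mean filling factor eta (the continuum site
  percolation transition sits between f = 2 and f = 3);
* a pure-geometry Monte-Carlo estimator of the continuum percolation
  threshold eta_c for overlapping equal discs, independent of the
  evolutionary model.

Replicate seeds are deterministic functions of (master_seed, value index,
replicate index), so every sweep is exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import SimParams, Trajectory, run_simulation

#: Sweepable SimParams fields.
SWEEPABLE = ("delta", "f")


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: grid of values x replicates."""

    base: SimParams
    sweep_variable: str
    values: tuple
    replicates: int
    generations: int | None = None  # overrides base.G when set
    master_seed: int = 0

    def __post_init__(self):
        if self.sweep_variable not in SWEEPABLE:
            raise ValueError(f"sweep_variable must be one of {SWEEPABLE}")
        vals = tuple(self.values)
        if len(vals) == 0:
            raise ValueError("values grid is empty")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("values grid must be strictly increasing")
        object.__setattr__(self, "values", vals)
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


@dataclass(frozen=True)
class SweepResult:
    """Per-run outcomes of a sweep plus across-replicate summaries.

    ``per_run`` has one row per (value, replicate) with the survival flag
    and the final-generation order parameters; extinct runs carry
    final_N = 0 and NaN R.
    """

    per_run: pd.DataFrame
    spec: SweepSpec

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation of each order parameter per value."""
        g = self.per_run.groupby("value")
        out = g.agg(
            survived_any=("survived", "any"),
            survived_all=("survived", "all"),
            mean_N=("final_N", "mean"),
            std_N=("final_N", "std"),
            mean_n_clusters=("final_n_clusters", "mean"),
            std_n_clusters=("final_n_clusters", "std"),
            mean_R=("final_R", "mean"),
            mean_eta=("final_eta", "mean"),
            std_eta=("final_eta", "std"),
        )
        return out.fillna({"std_N": 0.0, "std_n_clusters": 0.0, "std_eta": 0.0})


@dataclass(frozen=True)
class CriticalPointEstimate:
    """Critical death probability and R = 1 crossing for one mutability."""

    delta_c: float
    delta_R: float | None
    mu: float


@dataclass(frozen=True)
class PercThresholdEstimate:
    """Monte-Carlo continuum-percolation threshold for overlapping discs."""

    eta_c: float
    ci: tuple[float, float]
    box_size: float
    disc_radius: float
    replicates_per_eta: int
    eta_grid: tuple
    spanning_prob: tuple


def child_seed(master_seed: int, value_index: int, replicate: int) -> int:
    """Deterministic 31-bit replicate seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(value_index, replicate))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def run_sweep(spec: SweepSpec, trajectories: bool = False):
    """Run the whole grid; optionally also return the raw trajectories."""
    rows = []
    trajs: list[Trajectory] = []
    a = math.pi * spec.base.kappa**2
    area = spec.base.L * spec.base.L
    for vi, value in enumerate(spec.values):
        for rep in range(spec.replicates):
            seed = child_seed(spec.master_seed, vi, rep)
            overrides = {spec.sweep_variable: value, "seed": seed}
            if spec.generations is not None:
                overrides["G"] = spec.generations
            params = replace(spec.base, **overrides)
            traj = run_simulation(params)
            fin = traj.final
            rows.append(
                {
                    "value": value,
                    "replicate": rep,
                    "seed": seed,
                    "survived": traj.survived,
                    "final_N": fin.N,
                    "final_n_clusters": fin.n_clusters,
                    "final_R": fin.R,
                    # eta is linear in N, so keep it defined for all N
                    "final_eta": fin.N * a / area,
                    "final_spanning": fin.spanning,
                }
            )
            if trajectories:
                trajs.append(traj)
    result = SweepResult(pd.DataFrame(rows), spec)
    return (result, trajs) if trajectories else result


def sweep_delta(spec: SweepSpec) -> SweepResult:
    """Death-probability sweep (the non-equilibrium transition's control axis)."""
    if spec.sweep_variable != "delta":
        raise ValueError("sweep_delta requires sweep_variable='delta'")
    return run_sweep(spec)


def sweep_fitness(spec: SweepSpec) -> pd.DataFrame:
    """Fitness sweep; returns mean/std of the final filling factor per f."""
    if spec.sweep_variable != "f":
        raise ValueError("sweep_fitness requires sweep_variable='f'")
    if any(int(v) != v for v in spec.values):
        raise ValueError("fitness grid must be integer")
    result = run_sweep(spec)
    table = (
        result.per_run.groupby("value")["final_eta"]
        .agg(mean_eta="mean", std_eta="std")
        .reset_index()
        .rename(columns={"value": "f"})
    )
    return table.fillna({"std_eta": 0.0})


def estimate_delta_c(result: SweepResult, rule: str = "any") -> CriticalPointEstimate:
    """Largest swept delta at which the population survives the full run.

    ``rule`` decides what survival at one grid value means across
    replicates: "any" (default) or "all".
    """
    if result.spec.sweep_variable != "delta":
        raise ValueError("delta_c is defined for delta sweeps")
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    surv = result.per_run.groupby("value")["survived"].agg(rule)
    values = np.asarray(surv.index, dtype=float)
    flags = surv.to_numpy()
    if not flags.any():
        raise ValueError("no swept delta survived; delta_c lies below the grid")
    if flags.all():
        raise ValueError("every swept delta survived; delta_c lies above the grid")
    delta_c = float(values[flags].max())
    return CriticalPointEstimate(
        delta_c=delta_c, delta_R=r_transition_point(result), mu=result.spec.base.mu
    )


def r_transition_point(result: SweepResult) -> float | None:
    """Interpolated delta at which the mean final Clark–Evans R crosses 1.

    The mean at each grid value is taken over replicates with a defined R
    (i.e. surviving runs with at least two organisms). Returns None when no
    two consecutive defined means bracket 1.
    """
    mean_r = result.per_run.groupby("value")["final_R"].mean()
    values = np.asarray(mean_r.index, dtype=float)
    r = mean_r.to_numpy()
    for i in range(len(values) - 1):
        r0, r1 = r[i], r[i + 1]
        if not (np.isfinite(r0) and np.isfinite(r1)):
            continue
        if (r0 - 1.0) == 0.0:
            return float(values[i])
        if (r0 - 1.0) * (r1 - 1.0) < 0.0:
            t = (1.0 - r0) / (r1 - r0)
            return float(values[i] + t * (values[i + 1] - values[i]))
    return None


# ---------------------------------------------------------------------------
# Continuum-percolation Monte-Carlo oracle (pure geometry, no evolution)
# ---------------------------------------------------------------------------


def _spans_left_right(points: np.ndarray, radius: float, box: float) -> bool:
    """True when a chain of overlapping discs connects the left and right edges."""
    n = len(points)
    if n == 0:
        return False
    touches_left = points[:, 0] <= radius
    touches_right = points[:, 0] >= box - radius
    if not (touches_left.any() and touches_right.any()):
        return False
    tree = cKDTree(points)
    pairs = tree.query_pairs(2.0 * radius, output_type="ndarray")
    if len(pairs) == 0:
        # single disc wide enough to touch both edges is impossible for box > 2r
        return bool((touches_left & touches_right).any())
    m = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(m, directed=False)
    return bool(np.intersect1d(labels[touches_left], labels[touches_right]).size)


def _crossing(eta_grid: np.ndarray, probs: np.ndarray) -> float:
    """50% crossing of the spanning probability: logistic fit, linear fallback."""
    from scipy.optimize import curve_fit
    from scipy.special import expit

    def logistic(eta, c, w):
        return expit((eta - c) / w)

    try:
        popt, _ = curve_fit(
            logistic,
            eta_grid,
            probs,
            p0=(float(np.median(eta_grid)), 0.1),
            bounds=((eta_grid[0] - 1.0, 1e-4), (eta_grid[-1] + 1.0, 10.0)),
            maxfev=10000,
        )
        c = float(popt[0])
        if eta_grid[0] <= c <= eta_grid[-1]:
            return c
    except RuntimeError:
        pass
    above = np.flatnonzero(probs >= 0.5)
    if len(above) == 0 or above[0] == 0:
        raise ValueError("spanning probability does not cross 0.5 inside the grid")
    i = above[0] - 1
    t = (0.5 - probs[i]) / (probs[i + 1] - probs[i])
    return float(eta_grid[i] + t * (eta_grid[i + 1] - eta_grid[i]))


def estimate_continuum_threshold(
    box_size: float = 32.0,
    disc_radius: float = 1.0,
    eta_grid=None,
    replicates: int = 200,
    rng: np.random.Generator | int | None = None,
    n_boot: int = 200,
) -> PercThresholdEstimate:
    """Monte-Carlo threshold for left-right spanning of Poisson random discs.

    For each filling factor eta, discs are dropped as a homogeneous Poisson
    process of intensity eta / (pi r^2); a replicate spans when a connected
    chain of overlapping discs links discs touching the left and right box
    edges. eta_c is the 50% crossing of the spanning probability (logistic
    fit with a linear-interpolation fallback); the CI is a percentile
    bootstrap over the per-eta binomial counts.
    """
    if box_size < 8 * disc_radius:
        raise ValueError("box must be much larger than the disc radius")
    rng = np.random.default_rng(rng)
    if eta_grid is None:
        eta_grid = np.arange(0.90, 1.4001, 0.05)
    eta_grid = np.asarray(eta_grid, dtype=float)
    disc_area = math.pi * disc_radius**2
    area = box_size * box_size
    hits = np.zeros(len(eta_grid), dtype=int)
    for i, eta in enumerate(eta_grid):
        mean_count = eta * area / disc_area
        for _ in range(replicates):
            count = rng.poisson(mean_count)
            pts = rng.random((count, 2)) * box_size
            if _spans_left_right(pts, disc_radius, box_size):
                hits[i] += 1
    probs = hits / replicates
    eta_c = _crossing(eta_grid, probs)
    boots = []
    for _ in range(n_boot):
        p_star = rng.binomial(replicates, probs) / replicates
        try:
            boots.append(_crossing(eta_grid, p_star))
        except ValueError:
            continue
    if boots:
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (math.nan, math.nan)
    return PercThresholdEstimate(
        eta_c=eta_c,
        ci=ci,
        box_size=box_size,
        disc_radius=disc_radius,
        replicates_per_eta=replicates,
        eta_grid=tuple(eta_grid),
        spanning_prob=tuple(probs),
    )
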