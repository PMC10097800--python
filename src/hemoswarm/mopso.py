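"""Multi-objective particle swarm optimizer with a Pareto repository.

Constriction-factor velocity updates (no mutation operator of any kind),
an archive of mutually non-dominated solutions with an adaptive hypercube
grid over objective space, roulette leader selection biased toward sparse
cells, and random pruning from the densest cells when the archive is full.

The hemolysis search operates in (ln C, alpha, beta) coordinates: C spans
25 orders of magnitude in the wide domain, so bounds on C are transformed
to bounds on ln C.  The optimizer itself is dimension-agnostic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "MOPSOConfig",
    "ParetoRepository",
    "constriction",
    "dominates",
    "velocity_position_update",
    "pbest_update",
    "mopso_run",
    "mathematical_domain_bounds",
    "literature_domain_bounds",
]

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], tuple[float, float]]


def constriction(phi: float) -> tuple[float, float]:
    """Clerc-Kennedy constriction: inertia omega and merged learning factor c.

    omega = 1 / (phi - 1 + sqrt(phi^2 - 2*phi)),  c = omega * phi,  phi > 2.
    """
    if not (phi > 2.0):
        raise ValueError(f"phi must be > 2, got {phi}")
    omega = 1.0 / (phi - 1.0 + math.sqrt(phi * phi - 2.0 * phi))
    return omega, omega * phi


def dominates(a_objs: Sequence[float], b_objs: Sequence[float]) -> bool:
    """Pareto dominance (minimization): a <= b everywhere, < somewhere."""
    a = np.asarray(a_objs, dtype=float)
    b = np.asarray(b_objs, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal arity")
    return bool(np.all(a <= b) and np.any(a < b))


def mathematical_domain_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Wide search domain: C in [1e-30, 1e-5], alpha and beta in [0.1, 20]."""
    lb = np.array([math.log(1e-30), 0.1, 0.1])
    ub = np.array([math.log(1e-5), 20.0, 20.0])
    return lb, ub


def literature_domain_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Range spanned by published constant sets: C in [1e-9, 1e-7],
    alpha in [1.5, 2.5], beta in [0.5, 1.0]."""
    lb = np.array([math.log(1e-9), 1.5, 0.5])
    ub = np.array([math.log(1e-7), 2.5, 1.0])
    return lb, ub


def velocity_position_update(
    x: np.ndarray,
    v: np.ndarray,
    pbest: np.ndarray,
    leader: np.ndarray,
    omega: float,
    c: float,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One constriction update; returns (new position, new velocity).

    v' = omega*v + c*r1*(pbest - x) + c*r2*(leader - x), x' = x + v'.
    Components pushed past a bound are clamped to that bound while the
    velocity is maintained unchanged.
    """
    r1 = rng.uniform(size=x.shape)
    r2 = rng.uniform(size=x.shape)
    v_new = omega * v + c * r1 * (pbest - x) + c * r2 * (leader - x)
    x_new = np.clip(x + v_new, lb, ub)
    return x_new, v_new


def pbest_update(
    pbest: np.ndarray,
    pbest_objs: np.ndarray,
    x: np.ndarray,
    objs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Personal-best rule: replace if the current position dominates; keep
    if dominated; otherwise (mutual non-dominance) replace with probability
    1/2 from the seeded stream.  Returns (pbest, pbest_objs, replaced)."""
    if dominates(objs, pbest_objs):
        return x.copy(), np.array(objs, dtype=float), True
    if dominates(pbest_objs, objs):
        return pbest, pbest_objs, False
    if rng.uniform() < 0.5:
        return x.copy(), np.array(objs, dtype=float), True
    return pbest, pbest_objs, False


@dataclass
class MOPSOConfig:
    """Algorithm parameters.

    Reference configuration for the hemolysis problem: 100 particles,
    repository capacity 1000, 1000 iterations, phi = 2.01, 50 hypercubes
    per objective dimension.
    """

    lb: np.ndarray
    ub: np.ndarray
    n_particles: int = 100
    capacity: int = 1000
    t_max: int = 1000
    phi: float = 2.01
    n_grid: int = 50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.lb.shape != self.ub.shape or self.lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D arrays of equal shape")
        if not np.all(self.lb < self.ub):
            raise ValueError("lb must be < ub component-wise")
        if not (self.phi > 2.0):
            raise ValueError("phi must be > 2")
        for attr in ("n_particles", "capacity", "t_max", "n_grid"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be >= 1")

    @property
    def dim(self) -> int:
        return int(self.lb.size)


class ParetoRepository:
    """Archive of mutually non-dominated positions with a hypercube grid."""

    def __init__(self, capacity: int, n_grid: int):
        if capacity < 1 or n_grid < 1:
            raise ValueError("capacity and n_grid must be >= 1")
        self.capacity = int(capacity)
        self.n_grid = int(n_grid)
        self.positions: list[np.ndarray] = []
        self.objectives: list[np.ndarray] = []
        self._grid: Optional[np.ndarray] = None  # (n, n_obj) int bin indices

    def __len__(self) -> int:
        return len(self.positions)

    def objective_array(self) -> np.ndarray:
        return np.array(self.objectives).reshape(len(self.positions), -1)

    def position_array(self) -> np.ndarray:
        return np.array(self.positions).reshape(len(self.positions), -1)

    def insert(self, position: np.ndarray, objs: Sequence[float],
               rng: Optional[np.random.Generator] = None) -> bool:
        """Insert a candidate; returns True if it entered the archive.

        The candidate is rejected iff some entry strictly dominates it;
        entries it dominates are evicted.  Equal-objective entries co-exist
        (the solution structure is multi-modal, and distinct positions with
        identical objectives are exactly what the archive should retain).
        Grid indices are refreshed after any change, and the archive is
        pruned back to capacity by removing random members of maximally
        populated cells.
        """
        # copy: callers may pass views into arrays they mutate in place
        cand = np.array(objs, dtype=float)
        if not np.all(np.isfinite(cand)):
            raise ValueError(f"non-finite objectives {cand} at position {position}")
        if self.positions:
            all_objs = self.objective_array()
            dominated_by = np.all(all_objs <= cand, axis=1) & np.any(
                all_objs < cand, axis=1
            )
            if np.any(dominated_by):
                return False
            dominates_mask = np.all(cand <= all_objs, axis=1) & np.any(
                cand < all_objs, axis=1
            )
            if np.any(dominates_mask):
                keep = ~dominates_mask
                self.positions = [p for p, m in zip(self.positions, keep) if m]
                self.objectives = [o for o, m in zip(self.objectives, keep) if m]
        self.positions.append(np.array(position, dtype=float))
        self.objectives.append(cand)
        self.update_grid()
        while len(self.positions) > self.capacity:
            self._prune_one(rng if rng is not None else np.random.default_rng())
        return True

    def update_grid(self) -> np.ndarray:
        """Recompute hypercube bin indices from the current archive extent.

        The objective-space bounding box is inflated by 1% per side and cut
        into ``n_grid`` equal bins per dimension.
        """
        if not self.positions:
            raise ValueError("repository is empty")
        objs = self.objective_array()
        lo = objs.min(axis=0)
        hi = objs.max(axis=0)
        span = hi - lo
        pad = np.where(span > 0, 0.01 * span, 1.0)
        lo = lo - pad
        hi = hi + pad
        width = (hi - lo) / self.n_grid
        idx = np.floor((objs - lo) / width).astype(int)
        self._grid = np.clip(idx, 0, self.n_grid - 1)
        return self._grid

    def _cells(self) -> dict[tuple, list[int]]:
        if self._grid is None:
            self.update_grid()
        cells: dict[tuple, list[int]] = {}
        for i, key in enumerate(map(tuple, self._grid)):
            cells.setdefault(key, []).append(i)
        return cells

    def select_leader(self, rng: np.random.Generator) -> np.ndarray:
        """Roulette-wheel leader: cell weight 1/occupancy, uniform member."""
        if not self.positions:
            raise ValueError("repository is empty")
        cells = self._cells()
        keys = sorted(cells.keys())
        weights = np.array([1.0 / len(cells[k]) for k in keys])
        probs = weights / weights.sum()
        cell = keys[rng.choice(len(keys), p=probs)]
        member = cells[cell][rng.integers(len(cells[cell]))]
        return self.positions[member].copy()

    def _prune_one(self, rng: np.random.Generator) -> None:
        cells = self._cells()
        keys = sorted(cells.keys())
        occupancy = np.array([len(cells[k]) for k in keys])
        dense = [k for k, n in zip(keys, occupancy) if n == occupancy.max()]
        cell = dense[rng.integers(len(dense))]
        victim = cells[cell][rng.integers(len(cells[cell]))]
        del self.positions[victim]
        del self.objectives[victim]
        self.update_grid()

    def is_mutually_nondominated(self) -> bool:
        objs = self.objective_array()
        n = len(self.positions)
        for i in range(n):
            for j in range(n):
                if i != j and dominates(objs[i], objs[j]):
                    return False
        return True


def combine_repositories(
    repos: Sequence[ParetoRepository],
    capacity: Optional[int] = None,
    n_grid: Optional[int] = None,
    seed: Optional[int] = None,
) -> ParetoRepository:
    """Union of several archives followed by a dominance re-filter.

    This is how results of independent optimizer runs (e.g. over different
    search domains, or restarts) are merged into one repository.
    """
    if not repos:
        raise ValueError("repos must be non-empty")
    rng = np.random.default_rng(seed)
    out = ParetoRepository(
        capacity if capacity is not None else sum(r.capacity for r in repos),
        n_grid if n_grid is not None else repos[0].n_grid,
    )
    for r in repos:
        for pos, objs in zip(r.positions, r.objectives):
            out.insert(pos, objs, rng)
    return out


def mopso_run(objective_fn: Objective, config: MOPSOConfig) -> ParetoRepository:
    """Full optimizer loop; bit-reproducible for a fixed seed.

    Positions are initialized uniformly within [lb, ub], velocities
    uniformly within +/-(ub - lb).  Each iteration: select a leader per
    particle, apply the constriction velocity/position update, clamp
    positions to the violated bound (velocity maintained), evaluate, insert
    into the repository and update personal bests (mutual non-dominance
    resolved by a fair coin).  The only stochastic inputs are the
    initialization, r1/r2, leader and pbest tie-breaks, and pruning.
    """
    rng = np.random.default_rng(config.seed)
    omega, c = constriction(config.phi)
    lb, ub = config.lb, config.ub
    span = ub - lb
    dim = config.dim
    n = config.n_particles

    x = rng.uniform(lb, ub, size=(n, dim))
    v = rng.uniform(-span, span, size=(n, dim))

    def evaluate(pos: np.ndarray) -> np.ndarray:
        objs = np.asarray(objective_fn(pos), dtype=float)
        if not np.all(np.isfinite(objs)):
            raise RuntimeError(
                f"objective returned non-finite values {objs} at position {pos}"
            )
        return objs

    objs = np.array([evaluate(x[i]) for i in range(n)])
    pbest = x.copy()
    pbest_objs = objs.copy()

    repo = ParetoRepository(config.capacity, config.n_grid)
    for i in range(n):
        repo.insert(x[i], objs[i], rng)

    for t in range(config.t_max):
        for i in range(n):
            g = repo.select_leader(rng)
            x[i], v[i] = velocity_position_update(
                x[i], v[i], pbest[i], g, omega, c, lb, ub, rng
            )
            objs[i] = evaluate(x[i])
            repo.insert(x[i], objs[i], rng)
            pbest[i], pbest_objs[i], _ = pbest_update(
                pbest[i], pbest_objs[i], x[i], objs[i], rng
            )
        if (t + 1) % 10 == 0:
            best_fn = float(np.min(np.mean(repo.objective_array(), axis=1)))
            logger.info(
                "iteration %d: repository size %d, best F_n %.4f",
                t + 1,
                len(repo),
                best_fn,
            )
    return repo
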