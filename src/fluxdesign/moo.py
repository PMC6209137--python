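"""Pareto machinery and a speed-constrained multi-objective particle swarm.

All objectives are treated in *maximize* orientation: vector ``a``
dominates ``b`` iff ``a >= b`` componentwise with at least one strict
inequality. Non-dominated solutions are kept in a bounded external archive
truncated by crowding distance (boundary points carry infinite distance and
are never truncated), as in the SMPSO family of optimizers. An
exhaustive-grid evaluator serves as an exact oracle on discretized toy
problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "dominates",
    "pareto_filter",
    "ParetoArchive",
    "SwarmParams",
    "Problem",
    "FunctionProblem",
    "DesignProblem",
    "SnappedProblem",
    "smpso_optimize",
    "exhaustive_front",
    "crowding_distances",
    "hypervolume_2d",
]


def dominates(a, b) -> bool:
    """True iff a is at least as good everywhere and strictly better somewhere."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"objective sets differ: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def pareto_filter(points):
    """Indices of the non-dominated points, in stable input order."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        return []
    keep = []
    for i in range(pts.shape[0]):
        ge = np.all(pts >= pts[i], axis=1)
        gt = np.any(pts > pts[i], axis=1)
        if not np.any(ge & gt):
            keep.append(i)
    return keep


def crowding_distances(objs: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance; boundary points get +inf."""
    n, m = objs.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(objs[:, k], kind="stable")
        lo, hi = objs[order[0], k], objs[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = hi - lo
        if span <= 0:
            continue
        for idx in range(1, n - 1):
            dist[order[idx]] += (
                objs[order[idx + 1], k] - objs[order[idx - 1], k]
            ) / span
    return dist


@dataclass
class ParetoArchive:
    """Bounded archive of mutually non-dominated (objectives, payload) pairs."""

    capacity: int = 100
    entries: list = field(default_factory=list)  # [(objectives, payload)]
    version: int = 0  # bumped on every mutation (cache key for crowding)

    def __len__(self):
        return len(self.entries)

    @property
    def objectives(self) -> np.ndarray:
        if not self.entries:
            return np.empty((0, 0))
        return np.vstack([o for o, _ in self.entries])

    def add(self, objectives, payload=None) -> bool:
        """Insert if non-dominated; evict dominated members; truncate by crowding."""
        obj = np.asarray(objectives, float)
        if self.entries:
            objs = self.objectives
            if objs.shape[1] != obj.size:
                raise ValueError("objective sets differ between archive entries")
            ge = np.all(objs >= obj, axis=1)
            gt = np.any(objs > obj, axis=1)
            if np.any(ge & gt):
                return False
            le = np.all(objs <= obj, axis=1)
            lt = np.any(objs < obj, axis=1)
            dominated = le & lt
            if np.any(dominated):
                self.entries = [
                    e for e, d in zip(self.entries, dominated) if not d
                ]
        self.entries.append((obj, payload))
        if len(self.entries) > self.capacity:
            dist = crowding_distances(self.objectives)
            drop = int(np.argmin(dist))
            del self.entries[drop]
        self.version += 1
        return True

    def ideal_nadir(self):
        objs = self.objectives
        return objs.max(axis=0), objs.min(axis=0)


@dataclass(frozen=True)
class SwarmParams:
    """SMPSO search settings (jMetal-style defaults)."""

    swarm_size: int = 100
    iterations: int = 250
    archive_capacity: int = 100
    mutation_fraction: float = 0.15
    mutation_eta: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size <= 0 or self.iterations <= 0 or self.archive_capacity <= 0:
            raise ConfigurationError("swarm size, iterations and capacity must be > 0")


class Problem:
    """Protocol: bounds plus an evaluation returning (objectives, payload)."""

    lower: np.ndarray
    upper: np.ndarray

    def evaluate(self, x):  # pragma: no cover - interface
        raise NotImplementedError


class FunctionProblem(Problem):
    """Wrap a plain function f(x) -> objective array."""

    def __init__(self, lower, upper, fn):
        self.lower = np.asarray(lower, float)
        self.upper = np.asarray(upper, float)
        self._fn = fn

    def evaluate(self, x):
        return np.asarray(self._fn(np.asarray(x, float)), float), None


class DesignProblem(Problem):
    """Adapter exposing a DesignContext as a swarm problem.

    Positions are relaxed design vectors; evaluation repairs/rounds first so
    archive payloads are executable protocols.
    """

    def __init__(self, context):
        from .design import evaluate_design, repair_and_decode

        self.context = context
        self.lower = context.lower
        self.upper = context.upper
        self._repair = repair_and_decode
        self._evaluate = evaluate_design

    def evaluate(self, x):
        design = self._repair(x, self.context)
        result = self._evaluate(design, self.context)
        return result.values, result


class SnappedProblem(Problem):
    """Restrict another problem to per-variable grids (snap-to-nearest).

    Used to compare the stochastic search against the exhaustive-grid
    oracle on an identical discrete objective landscape.
    """

    def __init__(self, problem: Problem, grids):
        self.inner = problem
        self.grids = [np.asarray(g, float) for g in grids]
        if len(self.grids) != problem.lower.size:
            raise ConfigurationError("one grid per variable required")
        self.lower = problem.lower
        self.upper = problem.upper

    def snap(self, x):
        x = np.asarray(x, float)
        return np.array(
            [g[np.argmin(np.abs(g - xi))] for g, xi in zip(self.grids, x)]
        )

    def evaluate(self, x):
        return self.inner.evaluate(self.snap(x))


def _polynomial_mutation(x, lower, upper, eta, prob, rng):
    """Deb's polynomial mutation, applied per variable with probability prob."""
    y = x.copy()
    for i in range(y.size):
        if rng.random() >= prob:
            continue
        lo, hi = lower[i], upper[i]
        if hi <= lo:
            continue
        delta1 = (y[i] - lo) / (hi - lo)
        delta2 = (hi - y[i]) / (hi - lo)
        u = rng.random()
        mut_pow = 1.0 / (eta + 1.0)
        if u < 0.5:
            xy = 1.0 - delta1
            val = 2.0 * u + (1.0 - 2.0 * u) * xy ** (eta + 1.0)
            deltaq = val**mut_pow - 1.0
        else:
            xy = 1.0 - delta2
            val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * xy ** (eta + 1.0)
            deltaq = 1.0 - val**mut_pow
        y[i] = np.clip(y[i] + deltaq * (hi - lo), lo, hi)
    return y


def smpso_optimize(problem: Problem, params: SwarmParams | None = None, callback=None):
    """Speed-constrained multi-objective PSO with an external archive.

    Velocities use the constriction coefficient computed from acceleration
    constants drawn in U(1.5, 2.5) and are clamped to half the variable
    range; a fraction of particles undergoes polynomial mutation each
    iteration; personal bests update by Pareto dominance and global leaders
    are drawn from the archive by crowding-distance tournament. All
    randomness flows from one seeded generator, so a fixed seed reproduces
    the archive bitwise.

    Returns ``(archive, log)`` where ``log`` is a list of per-iteration
    records (iteration, archive size, ideal and nadir points).
    """
    params = params or SwarmParams()
    rng = np.random.default_rng(params.seed)
    lower, upper = problem.lower, problem.upper
    dim = lower.size
    span = upper - lower
    vmax = span / 2.0

    pos = lower + rng.random((params.swarm_size, dim)) * span
    vel = np.zeros_like(pos)
    archive = ParetoArchive(capacity=params.archive_capacity)

    def archive_add(o, x, payload):
        return archive.add(o, {"x": x.copy(), "payload": payload})

    objs = []
    for x in pos:
        o, payload = problem.evaluate(x)
        objs.append(o)
        archive_add(o, x, payload)
    objs = np.array(objs)
    pbest_pos = pos.copy()
    pbest_obj = objs.copy()

    log = []
    dist_cache = (-1, None)
    for it in range(params.iterations):
        for s in range(params.swarm_size):
            # leader by binary crowding tournament (distances recomputed
            # whenever the archive changed since last use)
            n = len(archive)
            i, j = int(rng.integers(0, n)), int(rng.integers(0, n))
            if i != j:
                if dist_cache[0] != archive.version:
                    dist_cache = (archive.version, crowding_distances(archive.objectives))
                arch_dist = dist_cache[1]
                lead_idx = i if arch_dist[i] >= arch_dist[j] else j
            else:
                lead_idx = i
            gbest = archive.entries[lead_idx][1]["x"]

            c1 = 1.5 + rng.random()
            c2 = 1.5 + rng.random()
            r1 = rng.random(dim)
            r2 = rng.random(dim)
            phi = c1 + c2
            if phi > 4.0:
                chi = 2.0 / (2.0 - phi - np.sqrt(phi * phi - 4.0 * phi))
            else:
                chi = 1.0
            v = chi * (
                vel[s]
                + c1 * r1 * (pbest_pos[s] - pos[s])
                + c2 * r2 * (gbest - pos[s])
            )
            v = np.clip(v, -vmax, vmax)
            x = pos[s] + v
            # keep inside the box; damp the velocity on the violated side
            below = x < lower
            above = x > upper
            v[below | above] *= 0.001
            x = np.clip(x, lower, upper)

            if rng.random() < params.mutation_fraction:
                x = _polynomial_mutation(
                    x, lower, upper, params.mutation_eta, 1.0 / dim, rng
                )

            o, payload = problem.evaluate(x)
            pos[s], vel[s] = x, v
            if dominates(o, pbest_obj[s]) or not dominates(pbest_obj[s], o):
                # replace unless the old personal best strictly dominates
                pbest_pos[s], pbest_obj[s] = x.copy(), o
            archive_add(o, x, payload)
        ideal, nadir = archive.ideal_nadir()
        record = {
            "iteration": it,
            "archive_size": len(archive),
            "ideal": ideal.tolist(),
            "nadir": nadir.tolist(),
        }
        log.append(record)
        if callback is not None:
            callback(record, archive)

    # archive entries are (objectives, {"x": position, "payload": evaluation})
    return archive, log


def exhaustive_front(problem: Problem, grids, guard: int = 1_000_000):
    """Exact Pareto set of a problem restricted to a finite grid.

    ``grids`` is one value list per variable; every combination is
    evaluated and filtered. Refuses grids with more than ``guard`` points.
    """
    grids = [np.asarray(g, float) for g in grids]
    if len(grids) != problem.lower.size:
        raise ConfigurationError("one grid per variable required")
    count = int(np.prod([g.size for g in grids]))
    if count > guard:
        raise ConfigurationError(
            f"grid has {count} points, exceeding the enumeration guard {guard}"
        )
    evaluated = []
    for combo in itertools.product(*grids):
        x = np.asarray(combo, float)
        o, payload = problem.evaluate(x)
        evaluated.append((o, {"x": x, "payload": payload}))
    keep = pareto_filter([o for o, _ in evaluated])
    archive = ParetoArchive(capacity=max(len(keep), 1))
    archive.entries = [evaluated[i] for i in keep]
    return archive


def hypervolume_2d(points, reference) -> float:
    """Dominated hypervolume of maximize-orientation 2-D points w.r.t. ref."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("hypervolume_2d needs 2-D objective vectors")
    ref = np.asarray(reference, float)
    keep = [i for i in pareto_filter(pts) ]
    front = pts[keep]
    front = front[np.argsort(-front[:, 0], kind="stable")]
    hv = 0.0
    prev_y = ref[1]
    for x, y in front:
        if x <= ref[0] or y <= prev_y:
            prev_y = max(prev_y, y)
            continue
        hv += (x - ref[0]) * (y - prev_y)
        prev_y = y
    return hv
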