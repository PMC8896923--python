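"""Hybrid GA -> PSO continuous optimizer ("GenPSO").

The iteration budget is split evenly: a genetic-algorithm phase (random
pairing, crossover, Gaussian mutation, wins-based tournament selection over
the mixed parent+offspring pool) runs first, and its final population seeds
a particle-swarm phase (pbest/gbest velocity updates with inertia and
clamping).  Fitness is minimized.  Both phases stop early when the best
fitness fails to improve by more than ``stagnation_eps`` across
``stagnation_window`` consecutive generations.

Everything is driven by a single ``numpy`` Generator, so a fixed seed gives
bit-identical runs.
"""

from __future__ import annotations

import configparser
import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Solution",
    "Particle",
    "GenPSOConfig",
    "EvaluationError",
    "init_population",
    "crossover",
    "mutate",
    "select_by_wins",
    "ga_phase",
    "pso_phase",
    "run_genpso",
    "write_trace_csv",
]

FitnessFn = Callable[[np.ndarray], float]


class EvaluationError(RuntimeError):
    """Raised when a fitness function returns a non-finite value."""


@dataclass
class Solution:
    position: np.ndarray
    fitness: float | None = None  # None = not yet evaluated

    def copy(self) -> "Solution":
        return Solution(self.position.copy(), self.fitness)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class GenPSOConfig:
    """Knobs of the hybrid optimizer.

    ``bounds`` is either a ``(lo, hi)`` pair applied to every coordinate or
    a ``(dim, 2)`` array of per-coordinate boxes.  ``mutation_sigma`` and
    ``vmax`` are fractions of the per-coordinate bound width.
    """

    dim: int
    bounds: tuple[float, float] | np.ndarray = (-1.0, 1.0)
    pop_size: int = 50
    total_iters: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.1
    opponents_fraction: float = 0.10
    stagnation_window: int = 50
    stagnation_eps: float = 1e-5
    inertia: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    vmax: float = 0.5
    seed: int = 0
    crossover_mode: str = "generic"  # "generic" | "node"
    node_layout: object | None = None  # needed for "node" mode

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.total_iters < 2:
            raise ValueError("total_iters must be >= 2")
        if not (0.0 < self.opponents_fraction <= 1.0):
            raise ValueError("opponents_fraction must be in (0, 1]")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.bounds_arrays()
        if np.any(lo >= hi):
            raise ValueError("every bound must satisfy lo < hi")

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        b = np.asarray(self.bounds, dtype=np.float64)
        if b.shape == (2,):
            lo = np.full(self.dim, b[0])
            hi = np.full(self.dim, b[1])
        elif b.shape == (self.dim, 2):
            lo, hi = b[:, 0].copy(), b[:, 1].copy()
        else:
            raise ValueError(f"bounds must be (lo, hi) or (dim, 2); got {b.shape}")
        return lo, hi

    @classmethod
    def from_ini(cls, path: str | Path, dim: int, **overrides) -> "GenPSOConfig":
        """Load numeric fields from a flat ``[genpso]`` (or default) INI section."""
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        section = parser["genpso"] if parser.has_section("genpso") else parser.defaults()
        kwargs: dict = {}
        int_fields = {"pop_size", "total_iters", "stagnation_window", "seed"}
        for key, raw in dict(section).items():
            if key == "bounds":
                lo, hi = (float(t) for t in raw.split(","))
                kwargs["bounds"] = (lo, hi)
            elif key in int_fields:
                kwargs[key] = int(raw)
            elif key == "crossover_mode":
                kwargs[key] = raw.strip()
            else:
                kwargs[key] = float(raw)
        kwargs.update(overrides)
        return cls(dim=dim, **kwargs)


def _evaluate(fitness: FitnessFn, sol: Solution) -> None:
    val = float(fitness(sol.position))
    if not math.isfinite(val):
        raise EvaluationError(
            f"fitness returned non-finite value {val!r} at position {sol.position!r}"
        )
    sol.fitness = val


def init_population(
    cfg: GenPSOConfig, rng: np.random.Generator
) -> list[Solution]:
    """P solutions drawn i.i.d. uniform inside the bound box, unevaluated."""
    lo, hi = cfg.bounds_arrays()
    pos = rng.uniform(lo, hi, size=(cfg.pop_size, cfg.dim))
    return [Solution(pos[i]) for i in range(cfg.pop_size)]


def crossover(
    p1: Solution,
    p2: Solution,
    rng: np.random.Generator,
    mode: str = "generic",
    layout: object | None = None,
) -> tuple[Solution, Solution]:
    """Produce two children from two parents.

    ``generic`` exchanges the tails after a uniform random cut point.
    ``node`` swaps the full incoming-weight slice (weights + bias) of one
    randomly chosen hidden or output node of a network genome; ``layout``
    must expose ``node_indices`` (a sequence of integer index arrays, one
    per node), as produced by :func:`imcodec.ffnn.genome_layout`.
    """
    a, b = p1.position.copy(), p2.position.copy()
    if a.shape != b.shape:
        raise ValueError("parents must have equal dimension")
    if mode == "generic":
        cut = int(rng.integers(0, a.size + 1))
        a[cut:], b[cut:] = p2.position[cut:].copy(), p1.position[cut:].copy()
    elif mode == "node":
        if layout is None or not hasattr(layout, "node_indices"):
            raise ValueError("node crossover requires a network genome layout")
        node = int(rng.integers(0, len(layout.node_indices)))
        idx = layout.node_indices[node]
        a[idx], b[idx] = p2.position[idx].copy(), p1.position[idx].copy()
    else:
        raise ValueError(f"unknown crossover mode {mode!r}")
    return Solution(a), Solution(b)


def mutate(
    s: Solution, cfg: GenPSOConfig, rng: np.random.Generator
) -> Solution:
    """Per-coordinate Gaussian mutation, clamped to the bounds.

    Each coordinate is perturbed with probability ``mutation_rate`` by
    N(0, (mutation_sigma * bound_width)^2) noise.
    """
    lo, hi = cfg.bounds_arrays()
    pos = s.position.copy()
    mask = rng.random(pos.size) < cfg.mutation_rate
    if mask.any() and cfg.mutation_sigma > 0:
        noise = rng.normal(0.0, cfg.mutation_sigma * (hi - lo))
        pos = np.where(mask, np.clip(pos + noise, lo, hi), pos)
    return Solution(pos)


def select_by_wins(
    mixed: Sequence[Solution], cfg: GenPSOConfig, rng: np.random.Generator
) -> list[Solution]:
    """Wins-based tournament over the mixed parent+offspring pool.

    Each candidate duels ``ceil(opponents_fraction * len(mixed))`` distinct
    random opponents (never itself); a win is a strictly lower fitness.
    The ``pop_size`` candidates with the most wins survive, ties broken by
    better fitness and then by lower index.
    """
    n = len(mixed)
    if any(s.fitness is None for s in mixed):
        raise RuntimeError("select_by_wins requires all fitness values evaluated")
    n_opp = min(math.ceil(cfg.opponents_fraction * n), n - 1)
    wins = np.zeros(n, dtype=np.int64)
    fits = np.array([s.fitness for s in mixed])
    for i in range(n):
        # distinct opponents excluding self
        opp = rng.choice(n - 1, size=n_opp, replace=False)
        opp = np.where(opp >= i, opp + 1, opp)
        wins[i] = int(np.sum(fits[i] < fits[opp]))
    order = sorted(range(n), key=lambda i: (-wins[i], fits[i], i))
    return [mixed[i] for i in order[: cfg.pop_size]]


class _StagnationTracker:
    """Stop when best-so-far improves < eps across a window of generations."""

    def __init__(self, window: int, eps: float) -> None:
        self.window = window
        self.eps = eps
        self.history: list[float] = []

    def update(self, best: float) -> bool:
        self.history.append(best)
        if len(self.history) <= self.window:
            return False
        return (self.history[-1 - self.window] - self.history[-1]) < self.eps


def ga_phase(
    fitness: FitnessFn,
    cfg: GenPSOConfig,
    rng: np.random.Generator,
    init: Sequence[np.ndarray] | None = None,
    trace: list[float] | None = None,
) -> list[Solution]:
    """Run floor(T/2) GA generations; return the final population sorted by fitness.

    ``init`` optionally injects starting positions (e.g. an elitist seed)
    into the initial random population, replacing its first members.
    """
    pop = init_population(cfg, rng)
    if init is not None:
        for i, position in enumerate(init):
            if i >= len(pop):
                break
            pop[i] = Solution(np.asarray(position, dtype=np.float64).copy())
    for sol in pop:
        _evaluate(fitness, sol)
    best = min(s.fitness for s in pop)
    stag = _StagnationTracker(cfg.stagnation_window, cfg.stagnation_eps)
    n_gen = cfg.total_iters // 2
    for _ in range(n_gen):
        order = rng.permutation(cfg.pop_size)
        offspring: list[Solution] = []
        i = 0
        while i + 1 < cfg.pop_size:
            pa, pb = pop[order[i]], pop[order[i + 1]]
            if rng.random() < cfg.crossover_rate:
                c1, c2 = crossover(
                    pa, pb, rng, mode=cfg.crossover_mode, layout=cfg.node_layout
                )
            else:
                c1, c2 = pa.copy(), pb.copy()
            offspring += [mutate(c1, cfg, rng), mutate(c2, cfg, rng)]
            i += 2
        if i < cfg.pop_size:  # odd population: clone+mutate the leftover parent
            offspring.append(mutate(pop[order[i]].copy(), cfg, rng))
        for sol in offspring:
            _evaluate(fitness, sol)
        mixed = [s.copy() for s in pop] + offspring
        mix_order = rng.permutation(len(mixed))
        mixed = [mixed[j] for j in mix_order]
        pop = select_by_wins(mixed, cfg, rng)
        best = min(best, min(s.fitness for s in pop))
        if trace is not None:
            trace.append(best)
        if stag.update(best):
            break
    return sorted(pop, key=lambda s: s.fitness)


def pso_phase(
    seedpop: Sequence[Solution],
    fitness: FitnessFn,
    cfg: GenPSOConfig,
    rng: np.random.Generator,
    trace: list[float] | None = None,
) -> tuple[Solution, list[float]]:
    """Particle swarm seeded from a GA population; returns (gbest, trace).

    Velocities start at zero and pbest at the seed positions; per
    iteration v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x) with
    per-coordinate uniform r1, r2, velocity clamped to +-vmax*range and
    position clamped to the bounds.  pbest/gbest update only on strict
    improvement.
    """
    if len(seedpop) == 0:
        raise ValueError("PSO phase requires a non-empty seed population")
    lo, hi = cfg.bounds_arrays()
    vlim = cfg.vmax * (hi - lo)
    pos = np.stack([s.position for s in seedpop]).astype(np.float64)
    fits = np.empty(len(seedpop))
    for i, s in enumerate(seedpop):
        if s.fitness is None:
            _evaluate(fitness, s)
        fits[i] = s.fitness
    vel = np.zeros_like(pos)
    pbest = pos.copy()
    pbest_fit = fits.copy()
    g = int(np.argmin(pbest_fit))
    gbest = pbest[g].copy()
    gbest_fit = float(pbest_fit[g])
    local_trace: list[float] = []
    stag = _StagnationTracker(cfg.stagnation_window, cfg.stagnation_eps)
    n_iter = cfg.total_iters - cfg.total_iters // 2
    for _ in range(n_iter):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = (
            cfg.inertia * vel
            + cfg.c1 * r1 * (pbest - pos)
            + cfg.c2 * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vlim, vlim)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(pos.shape[0]):
            val = float(fitness(pos[i]))
            if not math.isfinite(val):
                raise EvaluationError(
                    f"fitness returned non-finite value at position {pos[i]!r}"
                )
            if val < pbest_fit[i]:
                pbest_fit[i] = val
                pbest[i] = pos[i].copy()
                if val < gbest_fit:
                    gbest_fit = val
                    gbest = pos[i].copy()
        local_trace.append(gbest_fit)
        if trace is not None:
            trace.append(gbest_fit)
        if stag.update(gbest_fit):
            break
    return Solution(gbest, gbest_fit), local_trace


def run_genpso(
    fitness: FitnessFn,
    cfg: GenPSOConfig,
    init: Sequence[np.ndarray] | None = None,
) -> tuple[Solution, list[float]]:
    """GA phase, then PSO seeded with the GA's final population.

    Returns the overall best solution of both phases and the combined
    per-generation best-so-far trace.  Fully reproducible from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    pop = ga_phase(fitness, cfg, rng, init=init, trace=trace)
    ga_best = pop[0].copy()
    gbest, _ = pso_phase(pop, fitness, cfg, rng, trace=trace)
    best = gbest if gbest.fitness <= ga_best.fitness else ga_best
    return best, trace


def write_trace_csv(trace: Sequence[float], path: str | Path) -> None:
    """Dump an optimizer trace as (iteration, best_fitness) CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "best_fitness"])
        for i, v in enumerate(trace):
            writer.writerow([i, v])
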