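"""NSGA-II-style multi-objective evolutionary search over bounded parameters.

Canonical NSGA-II: Latin hypercube initialisation, fast non-dominated
sorting, crowding distance, binary tournament on (rank, crowding),
scattered (per-gene uniform mask) crossover, bounded Gaussian mutation
with reflection, and elitist (mu + lambda) truncation.  A single
objective degenerates to an elitist GA.  Everything is deterministic
given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import LileyParameters, ParameterBounds, SimulationConfig
from .objectives import DataFeatures, ObjectiveSpec, algorithm_objectives, evaluate_objectives

__all__ = [
    "Individual",
    "MOEAConfig",
    "FitResult",
    "latin_hypercube_init",
    "dominates",
    "non_dominated_sort",
    "crowding_distance",
    "select_optimal",
    "hypervolume",
    "minimize",
    "run_fit",
    "run_replicates",
]

_INF = float("inf")


@dataclass
class Individual:
    decision: np.ndarray
    objectives: np.ndarray | None = None
    rank: int = -1
    crowding: float = 0.0


@dataclass(frozen=True)
class MOEAConfig:
    """Search settings.  Defaults are desk-scale; cohort-scale settings
    (population 500, 50 generations, 5 repeats) are a configuration switch.
    """

    population_size: int = 100
    generations: int = 20
    crossover_fraction: float = 0.8
    tournament_size: int = 2
    mutation_sigma_frac: float = 0.05   # gene sd as a fraction of bound width
    mutation_sigma_final: float | None = None  # anneal to this by the last gen
    n_repeats: int = 3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class FitResult:
    pareto_set: list[Individual]
    optimum: Individual
    history: dict               # per-generation 'hypervolume', 'best_distance'
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# primitives

def latin_hypercube_init(bounds: ParameterBounds, n: int,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """n decision vectors with exactly one sample per stratum per dimension."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = len(bounds.lower)
    u = np.empty((n, g))
    for d in range(g):
        strata = rng.permutation(n)
        u[:, d] = (strata + rng.random(n)) / n
    return bounds.lower + u * bounds.width


def dominates(a, b) -> bool:
    """True iff a is no worse in every objective and strictly better in one."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal dimension")
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(objectives: np.ndarray) -> np.ndarray:
    """Rank assignment: rank 0 dominated by none, rank k only by ranks < k."""
    F = np.asarray(objectives, dtype=float)
    n = len(F)
    # pairwise dominance: dom[i, j] = i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    current = np.flatnonzero(n_dominators == 0)
    r = 0
    while len(current):
        ranks[current] = r
        for i in current:
            n_dominators[dom[i]] -= 1
        n_dominators[current] = -1
        current = np.flatnonzero(n_dominators == 0)
        r += 1
    return ranks


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front.

    Boundary members per objective get +inf; interior members the sum of
    range-normalised neighbour gaps.  Fronts of size <= 2 are all infinite.
    """
    F = np.asarray(objectives, dtype=float)
    n, d = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, _INF)
    for k in range(d):
        order = np.argsort(F[:, k], kind="stable")
        fk = F[order, k]
        span = fk[-1] - fk[0]
        dist[order[0]] = _INF
        dist[order[-1]] = _INF
        if span == 0:
            continue
        dist[order[1:-1]] += (fk[2:] - fk[:-2]) / span
    return dist


def select_optimal(pareto_objectives: np.ndarray) -> int:
    """Index of the front member closest to the origin after normalisation.

    Objectives are divided by their mean over the front; ties break to the
    lowest index.
    """
    F = np.asarray(pareto_objectives, dtype=float)
    if F.ndim != 2 or len(F) == 0:
        raise ValueError("pareto set must be a non-empty 2-d array")
    means = F.mean(axis=0)
    norm = np.where(means > 0, F / np.where(means > 0, means, 1.0), F)
    return int(np.argmin(np.linalg.norm(norm, axis=1)))


def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    pts = points[np.all(points < ref, axis=1)]
    if len(pts) == 0:
        return 0.0
    # pareto filter then sweep by f1 ascending / f2 descending
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    hv, best_f2 = 0.0, ref[1]
    for f1, f2 in pts:
        if f2 < best_f2:
            hv += (ref[0] - f1) * (best_f2 - f2)
            best_f2 = f2
    return hv


def hypervolume(front, ref_point) -> float:
    """Lebesgue measure of the union of boxes [point, ref]; exact, d <= 3.

    Points not strictly dominating the reference contribute nothing.
    """
    F = np.atleast_2d(np.asarray(front, dtype=float))
    ref = np.asarray(ref_point, dtype=float)
    d = F.shape[1]
    if d == 1:
        inside = F[:, 0] < ref[0]
        return float(ref[0] - F[inside, 0].min()) if inside.any() else 0.0
    if d == 2:
        return float(_hv2d(F, ref))
    if d == 3:
        pts = F[np.all(F < ref, axis=1)]
        if len(pts) == 0:
            return 0.0
        zs = np.unique(pts[:, 2])
        hv = 0.0
        levels = np.append(zs, ref[2])
        for i, z in enumerate(zs):
            depth = levels[i + 1] - z
            hv += depth * _hv2d(pts[pts[:, 2] <= z, :2], ref[:2])
        return float(hv)
    raise ValueError("hypervolume implemented for 1-3 objectives")


# ---------------------------------------------------------------------------
# generational loop over an arbitrary evaluator

Evaluator = Callable[[np.ndarray, np.ndarray], np.ndarray]
"""Maps (decision matrix (n, g), individual ids (n,)) -> objectives (n, d)."""


def _rank_crowd(pop: list[Individual]) -> None:
    F = np.array([ind.objectives for ind in pop])
    ranks = non_dominated_sort(F)
    for ind, r in zip(pop, ranks):
        ind.rank = int(r)
    for r in range(ranks.max() + 1):
        idx = np.flatnonzero(ranks == r)
        cd = crowding_distance(F[idx])
        for i, c in zip(idx, cd):
            pop[i].crowding = float(c)


def _truncate(pop: list[Individual], n: int) -> list[Individual]:
    order = sorted(range(len(pop)),
                   key=lambda i: (pop[i].rank, -pop[i].crowding, i))
    return [pop[i] for i in order[:n]]


def _tournament(pop: list[Individual], rng: np.random.Generator, k: int) -> Individual:
    idx = rng.integers(0, len(pop), size=k)
    best = min(idx, key=lambda i: (pop[i].rank, -pop[i].crowding, i))
    return pop[best]


def _make_offspring(pop: list[Individual], bounds: ParameterBounds,
                    cfg: MOEAConfig, rng: np.random.Generator,
                    progress: float = 0.0) -> np.ndarray:
    n, g = cfg.population_size, len(bounds.lower)
    n_cross = int(round(cfg.crossover_fraction * n))
    children = np.empty((n, g))
    for i in range(n_cross):
        p = _tournament(pop, rng, cfg.tournament_size).decision
        q = _tournament(pop, rng, cfg.tournament_size).decision
        mask = rng.random(g) < 0.5
        children[i] = np.where(mask, p, q)
    frac = cfg.mutation_sigma_frac
    if cfg.mutation_sigma_final is not None:
        # geometric anneal from the initial to the final mutation scale
        frac = frac * (cfg.mutation_sigma_final / frac) ** progress
    sigma = frac * bounds.width
    for i in range(n_cross, n):
        p = _tournament(pop, rng, cfg.tournament_size).decision
        child = p + rng.normal(0.0, sigma)
        # reflect at the bounds, then clip any residual excursion
        child = np.where(child < bounds.lower, 2 * bounds.lower - child, child)
        child = np.where(child > bounds.upper, 2 * bounds.upper - child, child)
        children[i] = np.clip(child, bounds.lower, bounds.upper)
    return children


def minimize(evaluator: Evaluator, bounds: ParameterBounds,
             config: MOEAConfig) -> FitResult:
    """Run the elitist generational loop and return the final front.

    Per-generation diagnostics: the hypervolume of the current rank-0 front
    against a reference fixed at 1.1x the componentwise maximum of the
    generation-0 objectives, and the best normalised Euclidean distance to
    the objective-space origin.
    """
    rng = np.random.default_rng(config.master_seed)
    X0 = latin_hypercube_init(bounds, config.population_size, rng)
    next_id = 0

    def evaluate(X: np.ndarray) -> list[Individual]:
        nonlocal next_id
        ids = np.arange(next_id, next_id + len(X))
        next_id += len(X)
        F = np.asarray(evaluator(X, ids), dtype=float)
        return [Individual(decision=x.copy(), objectives=f.copy())
                for x, f in zip(X, F)]

    pop = evaluate(X0)
    _rank_crowd(pop)
    F0 = np.array([ind.objectives for ind in pop])
    ref = 1.1 * F0.max(axis=0)
    initial_population = [Individual(decision=ind.decision.copy(),
                                     objectives=ind.objectives.copy())
                          for ind in pop]

    history: dict[str, list[float]] = {"hypervolume": [], "best_distance": []}

    def log_gen(pop: list[Individual]) -> None:
        front = np.array([ind.objectives for ind in pop if ind.rank == 0])
        history["hypervolume"].append(hypervolume(front, ref))
        means = np.maximum(front.mean(axis=0), np.finfo(float).tiny)
        history["best_distance"].append(
            float(np.min(np.linalg.norm(front / means, axis=1))))

    log_gen(pop)
    for _gen in range(config.generations):
        progress = _gen / max(config.generations - 1, 1)
        children = _make_offspring(pop, bounds, config, rng, progress)
        offspring = evaluate(children)
        pop = _truncate_combined(pop, offspring, config.population_size)
        log_gen(pop)

    front = [ind for ind in pop if ind.rank == 0]
    opt = front[select_optimal(np.array([ind.objectives for ind in front]))]
    return FitResult(
        pareto_set=front, optimum=opt, history=history,
        provenance={"config": config, "bounds": bounds,
                    "initial_population": initial_population})


def _truncate_combined(parents: list[Individual], offspring: list[Individual],
                       n: int) -> list[Individual]:
    pool = parents + offspring
    _rank_crowd(pool)
    pop = _truncate(pool, n)
    _rank_crowd(pop)
    return pop


# ---------------------------------------------------------------------------
# model-fitting front ends

def run_fit(data: DataFeatures, algorithm: str,
            moea_config: MOEAConfig | None = None,
            sim_config: SimulationConfig | None = None,
            bounds: ParameterBounds | None = None) -> FitResult:
    """Fit the neural mass model to one data epoch with a named algorithm.

    ``algorithm`` is one of SOEA20, SOEA45 (single-objective spectral fits)
    or MOEA20, MOEA45 (spectral + wHVG).  Fully reproducible from
    ``moea_config.master_seed``.
    """
    moea_config = moea_config or MOEAConfig()
    sim_config = sim_config or SimulationConfig(duration=2.0)
    bounds = bounds or ParameterBounds.physiological()
    specs = algorithm_objectives(algorithm, resolution=data.resolution)

    def evaluator(X: np.ndarray, ids: np.ndarray) -> np.ndarray:
        out = np.empty((len(X), len(specs)))
        for i, (x, ident) in enumerate(zip(X, ids)):
            params = LileyParameters.from_vector(x)
            out[i] = evaluate_objectives(
                params, data, specs, sim_config,
                n_repeats=moea_config.n_repeats,
                master_seed=moea_config.master_seed,
                individual_id=int(ident))
        return out

    result = minimize(evaluator, bounds, moea_config)
    result.provenance.update({
        "algorithm": algorithm, "sim_config": sim_config,
        "objectives": specs, "data_meta": data.meta,
    })
    return result


def run_replicates(data: DataFeatures, algorithm: str,
                   n_replicates: int,
                   moea_config: MOEAConfig | None = None,
                   sim_config: SimulationConfig | None = None,
                   bounds: ParameterBounds | None = None,
                   base_seed: int = 0) -> tuple[list[FitResult], np.ndarray]:
    """Independent replicate fits; pools each replicate's optimum.

    Returns (results, pooled) where ``pooled`` has one row per replicate:
    the selected optimum's decision vector.  Replicate seeds derive
    deterministically from ``base_seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    moea_config = moea_config or MOEAConfig()
    seeds = (np.random.SeedSequence(base_seed).generate_state(n_replicates)
             % (2 ** 31)).astype(int)
    results = []
    for s in seeds:
        cfg = MOEAConfig(**{**moea_config.__dict__, "master_seed": int(s)})
        results.append(run_fit(data, algorithm, cfg, sim_config, bounds))
    pooled = np.array([r.optimum.decision for r in results])
    return results, pooled
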