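"""Search for the per-class balance factors R.

Fitness of a candidate R is the cross-validated prediction error
1 − overall success rate of the fused cosine-KNN classifier, so smaller is
better.  The search has two stages:

1. **Greedy initial population.**  Repeat ``init_restarts`` times: draw a
   random order of the n coordinates; start from r_i = 0.5 everywhere; for
   each coordinate in turn, scan the grid 0, 0.01, ..., 1 (endpoints
   clamped into the open interval) and keep the value with the lowest
   fitness, updating coordinates sequentially.
2. **Real-coded genetic algorithm** seeded with those vectors: size-2
   tournament selection, arithmetic crossover, additive Gaussian mutation
   reflected into (ε, 1−ε), generational replacement with elitism, stopping
   at ``generations`` or after 20 stalled generations.

Coordinate scans and GA generations only change fusion weights, never the
underlying feature blocks, so the default fitness closure precomputes the
two Gram matrices A·Aᵀ and B·Bᵀ once; the cosine similarity of two vectors
fused with the same factor r is then the closed form

    (r²·G_A + (1−r)²·G_B) / sqrt(‖·‖·‖·‖)

and each fitness call is a pure O(N²) re-weighting.  A test asserts this
fast path agrees with the straightforward fuse-then-classify route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classify import _vote
from .evaluate import stratified_kfold
from .fusion import BalanceVector

_EPS = 1e-6

Fitness = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchConfig:
    """Tunables of the greedy + GA balance-factor search."""

    grid_step: float = 0.01
    init_restarts: int = 50
    population_size: int | None = None  # defaults to init_restarts
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sd: float = 0.05
    elitism: int = 1
    stall_generations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.grid_step <= 0.5):
            raise ValueError(f"grid_step must be in (0, 0.5], got {self.grid_step}")
        if self.init_restarts < 1:
            raise ValueError("init_restarts must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SearchResult:
    """Outcome of one GA run: best vector, its fitness and the trace."""

    best_R: BalanceVector
    best_fitness: float
    history: list[tuple[int, float, float]] = field(default_factory=list)
    evaluations: int = 0

    def save_trace(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("generation\tbest\tmean\n")
            for gen, best, mean in self.history:
                fh.write(f"{gen}\t{best!r}\t{mean!r}\n")


def make_cv_fitness(
    A: np.ndarray,
    B: np.ndarray,
    y: Sequence[int],
    K: int = 3,
    k: int = 1,
    seed: int = 0,
    mode: str = "candidate-class",
) -> Fitness:
    """CV-error fitness closure over fixed feature blocks A and B.

    Folds are drawn once (stratified, seeded) and frozen, so the closure is
    a deterministic function of R.  Returns 1 − overall success rate.

    ``mode`` picks how a held-out sample is weighted:

    * ``candidate-class`` (default): label-free — the similarity of a query
      to a training sample of class c fuses both with r_c, matching what
      the deployed classifier can actually compute.
    * ``true-label``: query and training vectors are each fused with their
      *own* class's factor before cosine.  Under extreme R this makes
      classes living in different blocks mutually near-orthogonal, so this
      fitness rewards routing each class to its informative block and its
      optima land near the ends of (0, 1).  Because the query's label
      enters its own weighting it is an optimization criterion, not an
      unbiased accuracy estimate.

    In both modes the cosine of two fused vectors is a closed form in the
    precomputed Gram matrices A·Aᵀ and B·Bᵀ, so a fitness call never
    re-encodes features.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    y = np.asarray(y, dtype=int)
    if mode not in ("true-label", "candidate-class"):
        raise ValueError(f"unknown fitness mode {mode!r}")
    GA_ = A @ A.T
    GB_ = B @ B.T
    nA = np.diag(GA_).copy()
    nB = np.diag(GB_).copy()
    folds = stratified_kfold(y, K=K, repeats=1, seed=seed)[0]
    N = y.size

    def fitness(R: np.ndarray) -> float:
        R = np.asarray(R, dtype=float)
        correct = 0
        for test_idx in folds:
            train_mask = np.ones(N, dtype=bool)
            train_mask[test_idx] = False
            train_idx = np.flatnonzero(train_mask)
            rt = R[y[train_idx] - 1]
            rt2, st2 = rt**2, (1.0 - rt) ** 2
            GAtt = GA_[np.ix_(test_idx, train_idx)]
            GBtt = GB_[np.ix_(test_idx, train_idx)]
            tn2 = rt2 * nA[train_idx] + st2 * nB[train_idx]
            if mode == "candidate-class":
                # both sides weighted by the training sample's class factor
                num = rt2 * GAtt + st2 * GBtt
                qn2 = nA[test_idx][:, None] * rt2 + nB[test_idx][:, None] * st2
            else:
                # each side weighted by its own class factor
                rq = R[y[test_idx] - 1]
                num = (rq[:, None] * rt) * GAtt + (
                    (1.0 - rq)[:, None] * (1.0 - rt)
                ) * GBtt
                qn2 = (rq**2 * nA[test_idx] + (1.0 - rq) ** 2 * nB[test_idx])[
                    :, None
                ] * np.ones_like(tn2)
            sims = num / np.sqrt(qn2 * tn2[None, :])
            pred = _vote(sims, y[train_idx], min(k, train_idx.size))
            correct += int(np.sum(pred == y[test_idx]))
        return 1.0 - correct / N

    return fitness


class _CountingFitness:
    def __init__(self, fn: Fitness):
        self.fn = fn
        self.calls = 0

    def __call__(self, R: np.ndarray) -> float:
        self.calls += 1
        return float(self.fn(R))


def _grid(step: float) -> np.ndarray:
    pts = np.arange(0.0, 1.0 + step / 2.0, step)
    return np.clip(pts, _EPS, 1.0 - _EPS)


def greedy_init(
    fitness: Fitness, n: int, config: SearchConfig | None = None
) -> list[BalanceVector]:
    """Greedy coordinate-scan construction of the GA's initial population.

    Produces exactly ``config.init_restarts`` balance vectors.  Each
    restart draws a fresh random coordinate order, starts from 0.5
    everywhere, and scans each coordinate over the clamped 0..1 grid,
    keeping the fitness-minimizing value before moving on.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 locations, got {n}")
    cfg = config if config is not None else SearchConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    grid = _grid(cfg.grid_step)
    population: list[BalanceVector] = []
    for _ in range(cfg.init_restarts):
        order = rng.permutation(n)
        R = np.full(n, 0.5)
        for coord in order:
            scores = np.empty(grid.size)
            for gi, val in enumerate(grid):
                R[coord] = val
                scores[gi] = fitness(R)
            R[coord] = grid[int(np.argmin(scores))]  # first minimum on ties
        population.append(BalanceVector(r=R.copy(), provenance="greedy-init"))
    return population


def _reflect(x: np.ndarray, lo: float = _EPS, hi: float = 1.0 - _EPS) -> np.ndarray:
    span = hi - lo
    z = np.abs((x - lo) % (2.0 * span))
    return lo + np.where(z > span, 2.0 * span - z, z)


def ga_optimize(
    initial_population: Sequence[BalanceVector],
    fitness: Fitness,
    config: SearchConfig | None = None,
) -> SearchResult:
    """Real-coded GA over balance vectors, minimizing the fitness error.

    Elitism guarantees the best-so-far never worsens; the run stops at
    ``generations`` or once the best fitness has stalled for
    ``stall_generations`` generations.
    """
    if not initial_population:
        raise ValueError("initial population is empty")
    cfg = config if config is not None else SearchConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    fit = _CountingFitness(fitness)

    pop = np.vstack([bv.r for bv in initial_population])
    n = pop.shape[1]
    pop_size = cfg.population_size or pop.shape[0]
    if pop.shape[0] < pop_size:  # pad by resampling with jitter
        extra = pop[rng.integers(0, pop.shape[0], pop_size - pop.shape[0])]
        pop = np.vstack([pop, _reflect(extra + rng.normal(0, cfg.mutation_sd, extra.shape))])
    scores = np.array([fit(ind) for ind in pop])

    best_idx = int(np.argmin(scores))
    best_R = pop[best_idx].copy()
    best_fit = float(scores[best_idx])
    history: list[tuple[int, float, float]] = [(0, best_fit, float(scores.mean()))]
    stall = 0

    for gen in range(1, cfg.generations + 1):
        elite_order = np.argsort(scores, kind="stable")[: cfg.elitism]
        children = [pop[i].copy() for i in elite_order]
        while len(children) < pop_size:
            parents = []
            for _ in range(2):  # two size-2 tournaments
                a, b = rng.integers(0, pop.shape[0], 2)
                parents.append(pop[a] if scores[a] <= scores[b] else pop[b])
            p1, p2 = parents
            if rng.random() < cfg.crossover_rate:
                beta = rng.random()
                child = beta * p1 + (1.0 - beta) * p2
            else:
                child = p1.copy()
            mutate = rng.random(n) < cfg.mutation_rate
            if mutate.any():
                child = child + mutate * rng.normal(0.0, cfg.mutation_sd, n)
            children.append(_reflect(child))
        pop = np.vstack(children)
        scores = np.array([fit(ind) for ind in pop])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_fit:
            best_fit = float(scores[gen_best])
            best_R = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        history.append((gen, best_fit, float(scores.mean())))
        if stall >= cfg.stall_generations:
            break

    return SearchResult(
        best_R=BalanceVector(r=best_R, provenance="ga-optimized"),
        best_fitness=best_fit,
        history=history,
        evaluations=fit.calls,
    )


def select_final_R(results: Sequence[SearchResult]) -> BalanceVector:
    """Pick the best result: minimum fitness, then fewest evaluations, then
    lexicographically smallest R."""
    if not results:
        raise ValueError("no search results to select from")
    return min(
        results,
        key=lambda res: (res.best_fitness, res.evaluations, tuple(res.best_R.r)),
    ).best_R


def optimize_balance(
    fitness: Fitness, n: int, config: SearchConfig | None = None
) -> SearchResult:
    """Full pipeline: greedy initial population, then GA refinement."""
    cfg = config if config is not None else SearchConfig()
    fit = _CountingFitness(fitness)
    population = greedy_init(fit, n, cfg)
    result = ga_optimize(population, fit, cfg)
    # include greedy-stage evaluations in the accounting
    result.evaluations = fit.calls
    return result
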