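"""Multi-objective maximization of all predicted responses over growing
conditions.

The decision space is the trained network's input space.  In *discrete* mode
a candidate is a factor-level triple (year, locality, fertilization) — only
2 × 3 × 6 = 36 combinations exist, so the exact Pareto front is computable by
exhaustive enumeration and serves as the oracle for the genetic algorithm.
In *relaxed* mode the genome is the raw 10-dimensional input vector with each
coordinate free in [0, 1], mirroring a continuous treatment of the encoded
factors.

The genetic algorithm is an NSGA-II-style loop: fast nondominated sorting,
crowding distance, binary tournament selection, uniform crossover and
per-gene mutation, with the returned front taken from an archive of every
individual evaluated during the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec
from .io import encode_levels
from .mlp import TrainedModel

__all__ = [
    "Candidate",
    "GAConfig",
    "ParetoResult",
    "enumerate_candidates",
    "pareto_filter",
    "ga_optimize",
    "best_condition_per_output",
]


@dataclass
class Candidate:
    """A growing-condition proposal with its predicted 30 responses."""

    year: str | None
    locality: str | None
    fertilization: str | None
    encoded: np.ndarray
    predicted: np.ndarray

    @property
    def levels(self) -> tuple:
        return (self.year, self.locality, self.fertilization)


@dataclass
class GAConfig:
    """Genetic-algorithm settings (defaults follow common NSGA-II practice;
    population 100 matches the study-scale run)."""

    population_size: int = 100
    generations: int = 200
    mode: str = "discrete"            # or "relaxed"
    crossover_prob: float = 0.9
    mutation_sigma: float = 0.1       # relaxed mode Gaussian step
    stall_generations: int = 20       # early stop when archive is stable

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population must be ≥ 4 and even")
        if self.mode not in ("discrete", "relaxed"):
            raise ValueError(f"mode must be 'discrete' or 'relaxed': {self.mode!r}")
        if self.generations < 0:
            raise ValueError("generations must be ≥ 0")


@dataclass
class ParetoResult:
    """Nondominated candidates found by the optimizer."""

    front: list[Candidate]
    generations_run: int
    population_size: int
    mode: str

    def to_frame(self, output_names: list[str]) -> pd.DataFrame:
        rows = []
        for c in self.front:
            row: dict = {
                "year": c.year, "locality": c.locality,
                "fertilization": c.fertilization,
            }
            row.update({f"x{i}": v for i, v in enumerate(c.encoded)})
            row.update(dict(zip(output_names, c.predicted)))
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_candidates(design: DesignSpec, model: TrainedModel) -> list[Candidate]:
    """All factor combinations with model predictions in original units."""
    cells = list(design.cells())
    X = np.vstack([encode_levels(y, l, f, design) for (y, l, f) in cells])
    pred = model.predict(X)
    return [
        Candidate(year=y, locality=l, fertilization=f, encoded=X[i], predicted=pred[i])
        for i, (y, l, f) in enumerate(cells)
    ]


def pareto_filter(points) -> list[int]:
    """Indices of the nondominated set (all objectives maximized).

    A point p is dominated iff some q satisfies q ≥ p componentwise with a
    strict inequality somewhere; exact duplicates never dominate each other,
    so every copy of a kept point is kept.
    """
    P = np.asarray(points, dtype=float)
    if P.size == 0:
        return []
    if P.ndim == 1:
        P = P[:, None]
    n = len(P)
    keep = []
    for i in range(n):
        geq = (P >= P[i]).all(axis=1)
        strict = (P > P[i]).any(axis=1)
        if not np.any(geq & strict):
            keep.append(i)
    return keep


# --- NSGA-II machinery ------------------------------------------------------


def _fast_nondominated_ranks(F: np.ndarray) -> np.ndarray:
    """Rank 0 = nondominated; higher ranks peel successive fronts."""
    n = len(F)
    dominated_by = [[] for _ in range(n)]
    dominates_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            i_ge = (F[i] >= F[j]).all()
            j_ge = (F[j] >= F[i]).all()
            if i_ge and (F[i] > F[j]).any():
                dominated_by[i].append(j)
                dominates_count[j] += 1
            elif j_ge and (F[j] > F[i]).any():
                dominated_by[j].append(i)
                dominates_count[i] += 1
    ranks = np.full(n, -1, dtype=int)
    current = [i for i in range(n) if dominates_count[i] == 0]
    r = 0
    while current:
        nxt = []
        for i in current:
            ranks[i] = r
            for j in dominated_by[i]:
                dominates_count[j] -= 1
                if dominates_count[j] == 0:
                    nxt.append(j)
        current, r = nxt, r + 1
    return ranks


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        span = F[order[-1], k] - F[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span == 0:
            continue
        for pos in range(1, n - 1):
            dist[order[pos]] += (F[order[pos + 1], k] - F[order[pos - 1], k]) / span
    return dist


class _Problem:
    """Genome handling for the two decision-space modes."""

    def __init__(self, design: DesignSpec, model: TrainedModel, mode: str,
                 sigma: float = 0.1):
        self.design = design
        self.model = model
        self.mode = mode
        self.sigma = sigma
        self.n_levels = (
            len(design.years), len(design.localities), len(design.fertilizations)
        )
        self.genome_length = 3 if mode == "discrete" else design.n_inputs
        self._cell_cache: dict[tuple, np.ndarray] = {}

    def random_genome(self, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "discrete":
            return np.array([rng.integers(k) for k in self.n_levels], dtype=float)
        return rng.uniform(0.0, 1.0, size=self.genome_length)

    def encode(self, genome: np.ndarray) -> np.ndarray:
        if self.mode == "relaxed":
            return np.asarray(genome, dtype=float)
        y, l, f = (int(g) for g in genome)
        key = (y, l, f)
        if key not in self._cell_cache:
            self._cell_cache[key] = encode_levels(
                self.design.years[y],
                self.design.localities[l],
                self.design.fertilizations[f],
                self.design,
            )
        return self._cell_cache[key]

    def candidate(self, genome: np.ndarray, predicted: np.ndarray) -> Candidate:
        if self.mode == "discrete":
            y, l, f = (int(g) for g in genome)
            return Candidate(
                year=self.design.years[y],
                locality=self.design.localities[l],
                fertilization=self.design.fertilizations[f],
                encoded=self.encode(genome),
                predicted=predicted,
            )
        return Candidate(
            year=None, locality=None, fertilization=None,
            encoded=np.asarray(genome, dtype=float), predicted=predicted,
        )

    def crossover(self, a, b, rng) -> tuple[np.ndarray, np.ndarray]:
        mask = rng.random(self.genome_length) < 0.5
        c1, c2 = a.copy(), b.copy()
        if self.mode == "discrete":
            c1[mask], c2[mask] = b[mask], a[mask]
        else:
            w = rng.random(self.genome_length)
            blend1 = w * a + (1 - w) * b
            blend2 = w * b + (1 - w) * a
            c1[mask], c2[mask] = blend1[mask], blend2[mask]
        return c1, c2

    def mutate(self, genome: np.ndarray, rng) -> np.ndarray:
        p = 1.0 / self.genome_length
        out = genome.copy()
        for g in range(self.genome_length):
            if rng.random() < p:
                if self.mode == "discrete":
                    out[g] = rng.integers(self.n_levels[g])
                else:
                    out[g] = np.clip(out[g] + rng.normal(0.0, self.sigma), 0.0, 1.0)
        return out


def _genome_key(genome: np.ndarray, mode: str) -> tuple:
    if mode == "discrete":
        return tuple(int(g) for g in genome)
    return tuple(np.round(np.asarray(genome, dtype=float), 12))


def ga_optimize(
    model: TrainedModel,
    design: DesignSpec,
    config: GAConfig | None = None,
    seed: int = 0,
) -> ParetoResult:
    """NSGA-II search for growing conditions maximizing all outputs at once.

    Every evaluated individual enters a deduplicated archive; the returned
    front is the nondominated subset of that archive, so nondominated points
    found in any generation cannot be lost.  The run stops early once the
    archive has been stable for ``config.stall_generations`` generations.
    Deterministic under ``seed``.
    """
    config = config or GAConfig()
    problem = _Problem(design, model, config.mode, sigma=config.mutation_sigma)
    rng = np.random.default_rng(seed)

    def evaluate(genomes: list[np.ndarray]) -> np.ndarray:
        X = np.vstack([problem.encode(g) for g in genomes])
        return model.predict(X)

    pop = [problem.random_genome(rng) for _ in range(config.population_size)]
    F = evaluate(pop)

    archive: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def archive_update(genomes, objs) -> bool:
        changed = False
        for g, f in zip(genomes, objs):
            key = _genome_key(g, config.mode)
            if key not in archive:
                archive[key] = (np.asarray(g, dtype=float), f)
                changed = True
        if changed:
            keys = list(archive)
            objs_all = np.vstack([archive[k][1] for k in keys])
            keep = set(pareto_filter(objs_all))
            pruned = {k: archive[k] for pos, k in enumerate(keys) if pos in keep}
            changed = set(pruned) != set(archive)
            archive.clear()
            archive.update(pruned)
            return True  # new evaluations may or may not alter the front
        return False

    def front_keys() -> frozenset:
        return frozenset(archive)

    archive_update(pop, F)
    prev_front = front_keys()
    stall = 0
    generations_run = 0

    for gen in range(config.generations):
        ranks = _fast_nondominated_ranks(F)
        crowd = np.zeros(len(pop))
        for r in np.unique(ranks):
            idx = np.where(ranks == r)[0]
            crowd[idx] = _crowding_distance(F[idx])

        def tournament() -> int:
            i, j = rng.integers(len(pop)), rng.integers(len(pop))
            if ranks[i] != ranks[j]:
                return i if ranks[i] < ranks[j] else j
            return i if crowd[i] >= crowd[j] else j

        offspring: list[np.ndarray] = []
        while len(offspring) < config.population_size:
            a, b = pop[tournament()], pop[tournament()]
            if rng.random() < config.crossover_prob:
                c1, c2 = problem.crossover(a, b, rng)
            else:
                c1, c2 = a.copy(), b.copy()
            offspring.append(problem.mutate(c1, rng))
            offspring.append(problem.mutate(c2, rng))
        offspring = offspring[: config.population_size]
        F_off = evaluate(offspring)
        archive_update(offspring, F_off)
        generations_run = gen + 1

        # environmental selection over parents + offspring
        union = pop + offspring
        F_union = np.vstack([F, F_off])
        ranks_u = _fast_nondominated_ranks(F_union)
        selected: list[int] = []
        for r in np.unique(ranks_u):
            idx = np.where(ranks_u == r)[0]
            if len(selected) + len(idx) <= config.population_size:
                selected.extend(idx.tolist())
            else:
                dist = _crowding_distance(F_union[idx])
                order = idx[np.argsort(-dist, kind="stable")]
                selected.extend(order[: config.population_size - len(selected)].tolist())
                break
        pop = [union[i] for i in selected]
        F = F_union[selected]

        cur_front = front_keys()
        stall = stall + 1 if cur_front == prev_front else 0
        prev_front = cur_front
        if stall >= config.stall_generations:
            break

    front = [
        problem.candidate(g, f) for g, f in archive.values()
    ]
    return ParetoResult(
        front=front,
        generations_run=generations_run,
        population_size=config.population_size,
        mode=config.mode,
    )


def best_condition_per_output(
    result: ParetoResult, output_names: list[str]
) -> dict[str, tuple[Candidate, float]]:
    """For each output, the front member with the maximal predicted value.

    Ties go to the earlier front member.
    """
    if not result.front:
        raise ValueError("Pareto front is empty")
    out: dict[str, tuple[Candidate, float]] = {}
    for j, name in enumerate(output_names):
        best_val = -np.inf
        best_c = None
        for c in result.front:  # strict > keeps the first member on ties
            if c.predicted[j] > best_val:
                best_val, best_c = float(c.predicted[j]), c
        out[name] = (best_c, best_val)
    return out
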