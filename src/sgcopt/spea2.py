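"""Elitist multi-objective evolutionary search (SPEA2) over code space.

The engine follows the classic SPEA2 loop: evaluate the union of population
and archive, assign strength/raw/density fitness, copy all non-dominated
individuals into a bounded archive (k-nearest-neighbour truncation on
overflow, fill with the best dominated individuals on underflow), stop after
``T`` generations returning the non-dominated subset of the final archive,
otherwise refill the mating pool by binary tournament and apply mutation and
crossover.  A single-objective variant replaces Pareto dominance with scalar
order and keeps a plain top-``N`` archive.

Direction handling: maximization runs negate objective values internally and
re-negate on output, so one minimizing core serves both searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .genetic_code import (
    GeneticCode,
    SENSE_CODON_INDICES,
    SGC_BLOCKS,
    _SGC_ARRAY,
    random_code,
)
from .objectives import (
    DEFAULT_ACCESSIONS,
    ObjectiveVector,
    batch_objectives,
    cost_matrix,
    load_builtin_indices,
    neighbor_pairs,
)
from .variation import (
    _bs_pos_crossover,
    _bs_swap,
    _us_amino_swap,
    _us_crossover,
    _us_point,
)

__all__ = [
    "ConfigError",
    "EngineConfig",
    "Individual",
    "ParetoArchive",
    "EvolveResult",
    "dominates",
    "assign_fitness",
    "environmental_selection",
    "tournament_fill",
    "evolve",
    "evolve_single",
    "run_repeats",
]


class ConfigError(ValueError):
    """An engine configuration is invalid."""


@dataclass(frozen=True)
class EngineConfig:
    """Run configuration for the evolutionary search.

    ``population_size`` (M), ``archive_cap`` (N_max) and ``generations`` (T)
    follow the published full-scale values M=2800, N_max=700, T=3000 by
    default; scale them down for desk runs.  ``mutation_prob`` /
    ``crossover_prob`` are the per-individual / per-pair application rates
    (0.9 and 0.3 in the reference runs).
    """

    population_size: int = 2800
    archive_cap: int = 700
    generations: int = 3000
    mutation_prob: float = 0.9
    crossover_prob: float = 0.3
    model: str = "BS"
    direction: str = "minimize"
    objectives: tuple[str, ...] = DEFAULT_ACCESSIONS
    seed: int = 0
    repeats: int = 1
    tournament: str = "binary"

    def validate(self) -> None:
        if min(self.population_size, self.archive_cap, self.generations) < 1:
            raise ConfigError("M, N_max and T must all be >= 1")
        for p in (self.mutation_prob, self.crossover_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("operator probabilities must be in [0, 1]")
        if self.model not in ("BS", "US"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.direction not in ("minimize", "maximize"):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if self.tournament not in ("binary", "proportional"):
            raise ConfigError(f"unknown tournament {self.tournament!r}")
        if self.repeats < 1 or len(self.objectives) < 1:
            raise ConfigError("need repeats >= 1 and >= 1 objective")


@dataclass
class Individual:
    """One evaluated code with its objective vector and SPEA2 fitness."""

    code: GeneticCode
    objectives: ObjectiveVector
    fitness: float | None = None


@dataclass
class ParetoArchive:
    """Bounded archive of (mutually non-dominated, at overflow) members."""

    members: list[Individual]
    generation: int = 0

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class EvolveResult:
    """Outcome of one run: final non-dominated set, archive and run log."""

    final: list[Individual]
    archive: ParetoArchive
    log: list[dict]
    config: EngineConfig


# --- Pareto machinery --------------------------------------------------------


def dominates(u, v, direction: str = "minimize") -> bool:
    """Pareto dominance: no component worse, at least one strictly better."""
    u = np.asarray(getattr(u, "values", u), dtype=float)
    v = np.asarray(getattr(v, "values", v), dtype=float)
    if u.shape != v.shape:
        raise ValueError("objective vectors differ in length")
    if direction == "maximize":
        u, v = -u, -v
    return bool((u <= v).all() and (u < v).any())


def _dominance_matrix(F: np.ndarray) -> np.ndarray:
    """Boolean matrix dom[i, j] = i dominates j (minimization)."""
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    return le & lt


def _distance_matrix(F: np.ndarray) -> np.ndarray:
    d2 = ((F[:, None, :] - F[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(np.maximum(d2, 0.0))


def assign_fitness(objectives: np.ndarray, k: int | None = None) -> np.ndarray:
    """SPEA2 fitness (lower is better) for a pool of objective vectors.

    Strength S(i) = number dominated by i; raw fitness R(i) = summed
    strengths of i's dominators; density D(i) = 1 / (sigma_i^k + 2) with
    sigma_i^k the Euclidean distance to the k-th nearest neighbour,
    k = round(sqrt(pool size)) unless given.  Non-dominated members have
    R = 0 and hence fitness < 1.
    """
    F = np.asarray(objectives, dtype=float)
    n = len(F)
    if n == 0:
        return np.empty(0)
    dom = _dominance_matrix(F)
    S = dom.sum(axis=1).astype(float)
    R = (dom * S[:, None]).sum(axis=0)
    if k is None:
        k = round(math.sqrt(n))
    k = min(max(k, 1), n - 1) if n > 1 else 1
    if n == 1:
        sigma = np.zeros(1)
    else:
        D = _distance_matrix(F)
        np.fill_diagonal(D, np.inf)
        sigma = np.partition(D, k - 1, axis=1)[:, k - 1]
    return R + 1.0 / (sigma + 2.0)


def _truncate(F: np.ndarray, cap: int, protect: np.ndarray) -> np.ndarray:
    """Indices kept after iterative k-NN truncation down to ``cap``.

    Repeatedly removes the member with the lexicographically smallest
    sorted-distance profile (so exact duplicates, at distance 0, go first).
    Members in ``protect`` (the per-objective minimizers) are exempt, which
    keeps the archive's ideal point monotone across generations.
    """
    n = len(F)
    alive = np.ones(n, dtype=bool)
    D = _distance_matrix(F)
    np.fill_diagonal(D, np.inf)

    # fast path: drop exact duplicates (zero nearest-neighbour distance)
    _, first = np.unique(F, axis=0, return_index=True)
    keep_first = np.zeros(n, dtype=bool)
    keep_first[first] = True
    for j in range(n - 1, -1, -1):
        if alive.sum() <= cap:
            break
        if not keep_first[j] and not protect[j]:
            alive[j] = False
            D[j, :] = np.inf
            D[:, j] = np.inf

    sigma = D.min(axis=1)
    nn = D.argmin(axis=1)
    while alive.sum() > cap:
        removable = alive & ~protect
        if not removable.any():  # cap smaller than the protected set
            removable = alive
        m = sigma[removable].min()
        cand = np.flatnonzero(removable & (sigma == m))
        if len(cand) > 1:
            # lexicographic comparison of full sorted-distance profiles
            profiles = [tuple(np.sort(D[c, alive])) for c in cand]
            j = cand[min(range(len(cand)), key=profiles.__getitem__)]
        else:
            j = cand[0]
        alive[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        stale = np.flatnonzero(alive & (nn == j))
        if stale.size:
            sigma[stale] = D[stale].min(axis=1)
            nn[stale] = D[stale].argmin(axis=1)
    return np.flatnonzero(alive)


def environmental_selection(
    objectives: np.ndarray, fitness: np.ndarray, cap: int
) -> np.ndarray:
    """Indices of the next archive (minimization orientation).

    All non-dominated candidates (fitness < 1) are copied; overflow is
    reduced by k-NN truncation, underflow filled with the best dominated
    candidates in ascending fitness order.
    """
    F = np.asarray(objectives, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    nd = np.flatnonzero(fitness < 1.0)
    if len(nd) > cap:
        Fnd = F[nd]
        protect = np.zeros(len(nd), dtype=bool)
        protect[np.argmin(Fnd, axis=0)] = True
        return nd[_truncate(Fnd, cap, protect)]
    if len(nd) < cap:
        dominated = np.flatnonzero(fitness >= 1.0)
        fill = dominated[np.argsort(fitness[dominated], kind="stable")]
        return np.concatenate([nd, fill[: cap - len(nd)]])
    return nd


def tournament_fill(
    fitness: np.ndarray,
    M: int,
    rng: np.random.Generator,
    mode: str = "binary",
) -> np.ndarray:
    """Mating-pool indices: M binary tournaments with replacement.

    ``binary`` copies the lower-fitness contestant (ties uniform);
    ``proportional`` copies the better one with probability
    f_other / (f_a + f_b), the probabilistic reading of the selection rule.
    """
    fitness = np.asarray(fitness, dtype=float)
    n = len(fitness)
    if n == 0:
        raise ValueError("archive is empty")
    a = rng.integers(n, size=M)
    b = rng.integers(n, size=M)
    if mode == "binary":
        coin = rng.random(M) < 0.5
        pick_a = (fitness[a] < fitness[b]) | (
            (fitness[a] == fitness[b]) & coin
        )
    elif mode == "proportional":
        tot = fitness[a] + fitness[b]
        p_a = np.where(tot > 0, fitness[b] / np.where(tot > 0, tot, 1.0), 0.5)
        pick_a = rng.random(M) < p_a
    else:
        raise ValueError(f"unknown tournament mode {mode!r}")
    return np.where(pick_a, a, b)


# --- engine internals --------------------------------------------------------

_BLOCK_OF_SENSE = np.empty(len(SENSE_CODON_INDICES), dtype=np.intp)
for _bi, _blk in enumerate(SGC_BLOCKS):
    for _ci in _blk:
        _BLOCK_OF_SENSE[np.flatnonzero(SENSE_CODON_INDICES == _ci)[0]] = _bi


def _expand_bs(perms: np.ndarray) -> np.ndarray:
    """(n, 20) block permutations -> (n, 64) codon assignments."""
    out = np.tile(_SGC_ARRAY, (len(perms), 1))
    out[:, SENSE_CODON_INDICES] = perms[:, _BLOCK_OF_SENSE]
    return out


def _init_population(model: str, M: int, rng: np.random.Generator):
    if model == "BS":
        return np.stack([rng.permutation(20) for _ in range(M)]).astype(np.int8)
    return np.stack(
        [random_code("US", rng).assignment for _ in range(M)]
    )


def _expand(pop: np.ndarray, model: str) -> np.ndarray:
    return _expand_bs(pop) if model == "BS" else pop


def _apply_operators(
    pop: np.ndarray, cfg: EngineConfig, rng: np.random.Generator
) -> np.ndarray:
    """Mutation then crossover on the mating pool (in place), per Fig-3 step 8."""
    M = len(pop)
    mutate = rng.random(M) < cfg.mutation_prob
    if cfg.model == "BS":
        for i in np.flatnonzero(mutate):
            _bs_swap(pop[i], rng)
    else:
        which = rng.random(M) < 0.5  # point mutation vs amino-acid swap
        for i in np.flatnonzero(mutate):
            if which[i]:
                _us_point(pop[i], rng)
            else:
                _us_amino_swap(pop[i], rng)
    order = rng.permutation(M)
    cross = rng.random(M // 2) < cfg.crossover_prob
    for j in np.flatnonzero(cross):
        ia, ib = order[2 * j], order[2 * j + 1]
        if cfg.model == "BS":
            c1, c2 = _bs_pos_crossover(pop[ia], pop[ib], rng)
        else:
            c1, c2 = _us_crossover(pop[ia], pop[ib], rng)
        pop[ia], pop[ib] = c1, c2
    return pop


def _cost_stack(cfg: EngineConfig, cost_matrices=None) -> np.ndarray:
    if cost_matrices is None:
        cost_matrices = [
            cost_matrix(idx) for idx in load_builtin_indices(cfg.objectives)
        ]
    stack = np.stack([m.costs for m in cost_matrices])
    return stack


def _make_individuals(
    assignments: np.ndarray,
    F_report: np.ndarray,
    fitness: np.ndarray | None,
    cfg: EngineConfig,
) -> list[Individual]:
    out = []
    for i in range(len(assignments)):
        code = GeneticCode(assignments[i].copy(), model=cfg.model)
        ov = ObjectiveVector(F_report[i].copy(), tuple(cfg.objectives))
        out.append(
            Individual(code, ov, None if fitness is None else float(fitness[i]))
        )
    return out


def evolve(config: EngineConfig, cost_matrices=None) -> EvolveResult:
    """Run the multi-objective SPEA2 loop; fully reproducible from the seed."""
    config.validate()
    sign = -1.0 if config.direction == "maximize" else 1.0
    stack = sign * _cost_stack(config, cost_matrices)
    pairs = neighbor_pairs(sense_only=True).pairs
    rng = np.random.default_rng(config.seed)
    M, cap, T = config.population_size, config.archive_cap, config.generations
    k_neighbor = round(math.sqrt(M + cap))

    pop = _init_population(config.model, M, rng)
    arch = pop[:0]
    arch_F = np.empty((0, stack.shape[0]))
    log: list[dict] = []

    t = 0
    while True:
        t += 1
        pop_F = batch_objectives(_expand(pop, config.model), stack, pairs)
        pool = np.concatenate([pop, arch])
        pool_F = np.concatenate([pop_F, arch_F])
        fitness = assign_fitness(pool_F, k=k_neighbor)
        sel = environmental_selection(pool_F, fitness, cap)
        arch, arch_F, arch_fit = pool[sel], pool_F[sel], fitness[sel]
        log.append(
            {
                "t": t,
                "archive_size": int(len(arch)),
                "ideal": (sign * arch_F.min(axis=0)).tolist(),
            }
        )
        if t >= T:
            nd_mask = ~_dominance_matrix(arch_F).any(axis=0)
            final_idx = np.flatnonzero(nd_mask)
            assignments = _expand(arch, config.model)
            members = _make_individuals(
                assignments, sign * arch_F, arch_fit, config
            )
            archive = ParetoArchive(members, generation=t)
            final = [members[i] for i in final_idx]
            return EvolveResult(final, archive, log, config)
        mating = tournament_fill(arch_fit, M, rng, config.tournament)
        pop = _apply_operators(arch[mating].copy(), config, rng)


def evolve_single(config: EngineConfig, cost_matrices=None) -> EvolveResult:
    """Single-objective variant: scalar order replaces Pareto dominance.

    The archive is simply the top ``archive_cap`` codes by objective value
    in the configured direction; returns the best code first in ``final``.
    """
    config.validate()
    if len(config.objectives) != 1 and cost_matrices is None:
        raise ConfigError("evolve_single needs exactly one objective")
    if cost_matrices is not None and len(cost_matrices) != 1:
        raise ConfigError("evolve_single needs exactly one cost matrix")
    sign = -1.0 if config.direction == "maximize" else 1.0
    stack = sign * _cost_stack(config, cost_matrices)
    pairs = neighbor_pairs(sense_only=True).pairs
    rng = np.random.default_rng(config.seed)
    M, cap, T = config.population_size, config.archive_cap, config.generations

    pop = _init_population(config.model, M, rng)
    arch = pop[:0]
    arch_v = np.empty(0)
    log: list[dict] = []

    t = 0
    while True:
        t += 1
        pop_v = batch_objectives(_expand(pop, config.model), stack, pairs)[:, 0]
        pool = np.concatenate([pop, arch])
        pool_v = np.concatenate([pop_v, arch_v])
        sel = np.argsort(pool_v, kind="stable")[:cap]
        arch, arch_v = pool[sel], pool_v[sel]
        log.append(
            {
                "t": t,
                "archive_size": int(len(arch)),
                "ideal": [float(sign * arch_v[0])],
            }
        )
        if t >= T:
            assignments = _expand(arch, config.model)
            members = _make_individuals(
                assignments, sign * arch_v[:, None], arch_v, config
            )
            archive = ParetoArchive(members, generation=t)
            return EvolveResult([members[0]], archive, log, config)
        mating = tournament_fill(arch_v, M, rng, config.tournament)
        pop = _apply_operators(arch[mating].copy(), config, rng)


def run_repeats(config: EngineConfig, cost_matrices=None) -> list[EvolveResult]:
    """Independent repeats with seeds ``seed+1 .. seed+repeats``.

    The aggregated optimized set is the union of the repeat archives
    (20 x 700 = 14,000 codes at the published multi-objective scale).
    """
    runner = evolve if len(config.objectives) > 1 else evolve_single
    out = []
    for r in range(1, config.repeats + 1):
        run_cfg = replace(config, seed=config.seed + r, repeats=1)
        out.append(runner(run_cfg, cost_matrices))
    return out
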