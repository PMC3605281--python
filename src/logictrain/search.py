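"""Genetic-algorithm bitstring optimisation, exhaustive oracle, model families.

The search operates on binary chromosomes and an arbitrary objective
``bits -> score``, so the discrete-time and fuzzy trainers reuse it by
appending extra genes to the model bitstring.  Every evaluated chromosome is
archived exactly once; after the search the archive yields the *family* of
models scoring within a relative tolerance of the optimum, and the per-gene
selection frequency across that family.  The empty and full chromosomes are
seeded into generation 0 so the baseline scores (empty model, full
PKN-derived model) are always reachable and bound the reported optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .boolean_engine import simulate_all
from .formats import MidasDataset
from .preprocess import Scaffold, StatusMap
from .scoring import ScoringConfig, theta_s, theta_f

__all__ = ["GAConfig", "SearchResult", "ga_optimize", "exhaustive_optimize",
           "boolean_objective", "optimize_boolean"]


@dataclass(frozen=True)
class GAConfig:
    """Knobs of the genetic algorithm.

    ``mutation_rate`` is the per-bit flip probability (default 0.5/r, set at
    run time when None).  ``tolerance`` is relative: the reported family is
    every evaluated model with score <= (1 + tolerance) * best.
    """

    pop_size: int = 50
    generations: int = 500
    mutation_rate: float | None = None
    crossover_rate: float = 0.8
    elitism: int = 2
    stall_generations: int = 100
    seed: int = 0
    tolerance: float = 0.1

    def __post_init__(self):
        if min(self.pop_size, self.generations, self.elitism,
               self.stall_generations) < 1:
            raise ValueError("counts must be >= 1")
        if not (0 <= self.crossover_rate <= 1):
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutation_rate is not None and not (0 <= self.mutation_rate <= 1):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class SearchResult:
    """Best model, evaluation archive, tolerance family and gene frequencies."""

    best_bits: np.ndarray
    best_score: float
    archive: dict[tuple[int, ...], float]
    family: np.ndarray
    frequencies: np.ndarray
    tolerance: float
    generations_run: int = 0

    @property
    def n_evaluated(self) -> int:
        return len(self.archive)

    def archive_rows(self):
        for bits, score in self.archive.items():
            yield bits, score


def _family_and_freq(archive, best_score, tolerance, n_bits):
    limit = (1.0 + tolerance) * best_score
    members = [b for b, s in archive.items() if s <= limit + 1e-12]
    family = np.array(members, dtype=int).reshape(len(members), n_bits)
    freq = family.mean(axis=0) if len(members) else np.zeros(n_bits)
    return family, freq


def _normalize_mask(search_mask, n_bits):
    """mask entry: None/-1 = free, 0/1 = fixed to that value."""
    fixed = np.zeros(n_bits, dtype=bool)
    values = np.zeros(n_bits, dtype=int)
    if search_mask is None:
        return fixed, values
    arr = np.asarray(
        [(-1 if v is None else int(v)) for v in search_mask], dtype=int
    )
    if arr.shape != (n_bits,):
        raise ValueError("search_mask length mismatch")
    fixed = arr >= 0
    values[fixed] = arr[fixed]
    return fixed, values


def ga_optimize(
    n_bits: int,
    objective,
    cfg: GAConfig,
    search_mask=None,
    seeds=(),
) -> SearchResult:
    """Seeded, reproducible GA over ``{0,1}^n_bits``.

    ``search_mask`` pins user-fixed genes (entries 0/1; None = searched).
    ``seeds`` are extra chromosomes injected into generation 0 (on top of the
    always-injected empty and full chromosomes).
    """
    rng = np.random.default_rng(cfg.seed)
    fixed, fixed_vals = _normalize_mask(search_mask, n_bits)
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 0.5 / max(n_bits, 1)

    archive: dict[tuple[int, ...], float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        key = tuple(int(b) for b in chrom)
        if key not in archive:
            archive[key] = float(objective(np.array(key, dtype=int)))
        return archive[key]

    def constrain(chrom: np.ndarray) -> np.ndarray:
        chrom = chrom.astype(int)
        chrom[fixed] = fixed_vals[fixed]
        return chrom

    if fixed.all():
        only = constrain(np.zeros(n_bits, dtype=int))
        warnings.warn("search_mask fixes every gene; nothing to optimise")
        evaluate(only)
        family, freq = _family_and_freq(archive, archive[tuple(only)],
                                        cfg.tolerance, n_bits)
        return SearchResult(only, archive[tuple(only)], archive, family, freq,
                            cfg.tolerance, 0)

    pop = [constrain(rng.integers(0, 2, n_bits)) for _ in range(cfg.pop_size)]
    injected = [np.zeros(n_bits, dtype=int), np.ones(n_bits, dtype=int)]
    injected += [np.asarray(s, dtype=int) for s in seeds]
    for i, chrom in enumerate(injected[: cfg.pop_size]):
        pop[i] = constrain(chrom.copy())

    scores = np.array([evaluate(c) for c in pop])
    best_idx = int(np.argmin(scores))
    best_bits, best_score = pop[best_idx].copy(), float(scores[best_idx])
    stall = 0
    gens = 0

    for gen in range(cfg.generations):
        gens = gen + 1
        order = np.argsort(scores, kind="stable")
        elite = [pop[i].copy() for i in order[: cfg.elitism]]
        children = list(elite)
        while len(children) < cfg.pop_size:
            # binary tournament selection
            a, b = rng.integers(0, cfg.pop_size, 2)
            p1 = pop[a] if scores[a] <= scores[b] else pop[b]
            a, b = rng.integers(0, cfg.pop_size, 2)
            p2 = pop[a] if scores[a] <= scores[b] else pop[b]
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(n_bits) < 0.5  # uniform crossover
                c1[swap], c2[swap] = p2[swap], p1[swap]
            for c in (c1, c2):
                flips = rng.random(n_bits) < mut
                c[flips] ^= 1
                children.append(constrain(c))
        pop = children[: cfg.pop_size]
        scores = np.array([evaluate(c) for c in pop])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score - 1e-15:
            best_score = float(scores[gen_best])
            best_bits = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        if stall >= cfg.stall_generations:
            break

    family, freq = _family_and_freq(archive, best_score, cfg.tolerance, n_bits)
    return SearchResult(best_bits, best_score, archive, family, freq,
                        cfg.tolerance, gens)


def exhaustive_optimize(
    n_bits: int,
    objective,
    search_mask=None,
    tolerance: float = 0.1,
    max_free_bits: int = 20,
) -> SearchResult:
    """Global optimum by enumeration (oracle; refuses > ``max_free_bits``)."""
    fixed, fixed_vals = _normalize_mask(search_mask, n_bits)
    free = np.flatnonzero(~fixed)
    if len(free) > max_free_bits:
        raise ValueError(
            f"{len(free)} free bits exceeds the exhaustive-search guard "
            f"({max_free_bits})"
        )
    archive: dict[tuple[int, ...], float] = {}
    best_bits, best_score = None, np.inf
    chrom = np.zeros(n_bits, dtype=int)
    chrom[fixed] = fixed_vals[fixed]
    for code in range(2 ** len(free)):
        for j, pos in enumerate(free):
            chrom[pos] = (code >> j) & 1
        score = float(objective(chrom.copy()))
        archive[tuple(int(b) for b in chrom)] = score
        if score < best_score:
            best_score, best_bits = score, chrom.copy()
    family, freq = _family_and_freq(archive, best_score, tolerance, n_bits)
    return SearchResult(best_bits, best_score, archive, family, freq, tolerance)


# ---------------------------------------------------------------------------
# Boolean steady-state training (the default formalism)


def boolean_objective(
    scaffold: Scaffold,
    data: MidasDataset,
    status: StatusMap,
    scoring: ScoringConfig,
    time_index: int = 1,
    max_iter: int | None = None,
):
    """Objective closure: bits -> theta at one pseudo-steady-state time."""

    def objective(bits: np.ndarray) -> float:
        sim = simulate_all(scaffold, bits, data, status, max_iter=max_iter)
        return (
            theta_f(sim, data, status, time_index, scoring.na_penalty)
            + scoring.alpha * theta_s(scaffold, bits)
        )

    return objective


def optimize_boolean(
    scaffold: Scaffold,
    data: MidasDataset,
    status: StatusMap,
    scoring: ScoringConfig,
    ga: GAConfig,
    time_index: int = 1,
    search_mask=None,
) -> SearchResult:
    """Train a Boolean steady-state model with the GA."""
    obj = boolean_objective(scaffold, data, status, scoring, time_index)
    return ga_optimize(scaffold.n_gates, obj, ga, search_mask=search_mask)
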