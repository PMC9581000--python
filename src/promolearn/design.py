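"""Promoter design: search sequence space against a trained estimator.

A genetic algorithm (tournament selection, two-point crossover,
per-position point mutation, elitism of one) minimizes a fitness over
fixed-length ACGT sequences:

* regression — |predicted activity − target value|, optionally plus a
  weighted normalized Hamming distance to reference sequence(s);
* classification — the normalized Hamming distance to the nearest
  reference sequence, plus a constant penalty of 10.0 whenever the
  predicted class differs from the target class. The additive penalty
  (rather than hard rejection) lets early, fully infeasible populations
  still evolve toward the feasible region.

Sequences already present in the training library are assigned infinite
fitness and additionally filtered from the results, so a design never
reproduces a library member. For small sequence lengths (R <= 10) an
exhaustive search over all 4^R sequences serves as an oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import SearchSpaceError
from .library import NUCLEOTIDES, PromoterLibrary, encode_sequences
from .stats import consensus_sequence
from .train import TrainedEstimator

#: Penalty added to classification fitness when the predicted class misses
#: the target class (distances live in [0, 1], so 10 dominates them).
CLASS_PENALTY = 10.0


@dataclass(frozen=True)
class DesignTarget:
    """Desired activity for the search.

    Exactly one of ``target_value`` (regression) or ``target_class``
    (classification) is set. ``references`` are the sequences to stay
    close to; when empty the library consensus is used. ``distance_weight``
    adds a distance term to the regression fitness (0 disables it).
    """

    mode: str  # "regression" | "classification"
    target_value: float | None = None
    target_class: int | None = None
    references: tuple[str, ...] = ()
    distance_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in {"regression", "classification"}:
            raise ValueError(f"unknown design mode {self.mode!r}")
        if self.mode == "regression" and self.target_value is None:
            raise ValueError("regression design needs target_value")
        if self.mode == "classification" and self.target_class is None:
            raise ValueError("classification design needs target_class")
        if self.target_value is not None and self.target_class is not None:
            raise ValueError("set exactly one of target_value / target_class")


@dataclass(frozen=True)
class GAParams:
    """Genetic-algorithm settings (conventional defaults, all overridable)."""

    population_size: int = 100
    generations: int = 50
    mutation_prob_per_position: float | None = None  # default 1/R
    crossover_prob: float = 0.7
    tournament_size: int = 3
    seed: int = 0
    n_results: int = 10

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.mutation_prob_per_position is not None and not (
            0.0 <= self.mutation_prob_per_position <= 1.0
        ):
            raise ValueError("mutation probability must lie in [0, 1]")


@dataclass(frozen=True)
class DesignResult:
    """Top designed sequences with predictions and reference distances."""

    sequences: tuple[str, ...]
    predicted: np.ndarray
    distance_to_reference: np.ndarray
    fitness: np.ndarray
    fitness_history: np.ndarray  # best fitness per generation


def _decode(codes: np.ndarray) -> list[str]:
    lut = np.array(list("ACGT"))
    return ["".join(row) for row in lut[codes]]


def _reference_codes(
    target: DesignTarget, lib: PromoterLibrary | None, R: int
) -> np.ndarray:
    refs = target.references
    if not refs and lib is not None and lib.size:
        refs = (consensus_sequence(lib),)
    if not refs:
        return np.empty((0, R), dtype=np.int8)
    for ref in refs:
        if len(ref) != R:
            raise ValueError(
                f"reference length {len(ref)} does not match sequence length {R}"
            )
    return encode_sequences(list(refs))


def _min_reference_distance(codes: np.ndarray, ref_codes: np.ndarray) -> np.ndarray:
    """Per-sequence minimum normalized Hamming distance to any reference."""
    if ref_codes.shape[0] == 0:
        return np.zeros(codes.shape[0])
    dists = (codes[:, None, :] != ref_codes[None, :, :]).mean(axis=2)
    return dists.min(axis=1)


def evaluate_fitness(
    est: TrainedEstimator,
    codes: np.ndarray,
    target: DesignTarget,
    ref_codes: np.ndarray,
    library_sequences: frozenset[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fitness (lower is better), predictions and reference distances."""
    seqs = _decode(codes)
    predicted = est.predict(seqs)
    dist = _min_reference_distance(codes, ref_codes)
    if target.mode == "regression":
        fitness = np.abs(
            np.asarray(predicted, dtype=float) - target.target_value
        )
        if target.distance_weight:
            fitness = fitness + target.distance_weight * dist
    else:
        miss = np.asarray(predicted) != target.target_class
        fitness = dist + CLASS_PENALTY * miss
    if library_sequences:
        in_lib = np.array([s in library_sequences for s in seqs])
        fitness = np.where(in_lib, np.inf, fitness)
    return fitness, predicted, dist


def design_promoters(
    est: TrainedEstimator,
    target: DesignTarget,
    params: GAParams,
    lib: PromoterLibrary | None = None,
) -> DesignResult:
    """Search for new promoter sequences with the desired activity.

    Runs a seeded genetic algorithm over length-R ACGT space. The initial
    population is uniform random; each generation applies tournament
    selection, two-point crossover, per-position point mutation (to a
    different nucleotide) and elitism of one. Returns the
    ``params.n_results`` best distinct feasible sequences, none of which
    occurs in *lib*.
    """
    if est.target_spec.task != target.mode:
        raise ValueError(
            f"estimator task {est.target_spec.task!r} does not match design "
            f"mode {target.mode!r}"
        )
    R = len(est.position_labels)
    rng = np.random.default_rng(params.seed)
    mut_p = (
        params.mutation_prob_per_position
        if params.mutation_prob_per_position is not None
        else 1.0 / R
    )
    ref_codes = _reference_codes(target, lib, R)
    lib_seqs = frozenset(lib.sequences) if lib is not None else frozenset()

    pop = rng.integers(0, 4, size=(params.population_size, R), dtype=np.int8)
    fitness, predicted, dist = evaluate_fitness(
        est, pop, target, ref_codes, lib_seqs
    )

    # archive of the best distinct feasible candidates seen in any generation
    archive: dict[str, tuple[float, float, float]] = {}

    def _archive(codes, fit, pred, d):
        for row, f, p, dd in zip(codes, fit, pred, d):
            if not np.isfinite(f):
                continue
            s = "".join(NUCLEOTIDES[b] for b in row)
            if s not in archive or f < archive[s][0]:
                archive[s] = (float(f), float(p), float(dd))

    _archive(pop, fitness, predicted, dist)
    history = [float(fitness.min())]

    for _ in range(params.generations):
        elite_idx = int(np.argmin(fitness))
        elite = pop[elite_idx].copy()
        # tournament selection
        draws = rng.integers(
            0, params.population_size,
            size=(params.population_size, params.tournament_size),
        )
        winners = draws[np.arange(params.population_size),
                        np.argmin(fitness[draws], axis=1)]
        children = pop[winners].copy()
        # two-point crossover on consecutive pairs
        for i in range(0, params.population_size - 1, 2):
            if rng.random() < params.crossover_prob:
                a, b = sorted(rng.integers(0, R, size=2))
                if a != b:
                    tmp = children[i, a:b].copy()
                    children[i, a:b] = children[i + 1, a:b]
                    children[i + 1, a:b] = tmp
        # point mutation: shift to one of the other 3 nucleotides
        mask = rng.random(children.shape) < mut_p
        shift = rng.integers(1, 4, size=children.shape, dtype=np.int8)
        children = np.where(mask, (children + shift) % 4, children).astype(np.int8)
        children[0] = elite  # elitism of 1
        pop = children
        fitness, predicted, dist = evaluate_fitness(
            est, pop, target, ref_codes, lib_seqs
        )
        _archive(pop, fitness, predicted, dist)
        history.append(min(history[-1], float(fitness.min())))

    ranked = sorted(archive.items(), key=lambda kv: (kv[1][0], kv[0]))
    feasible = ranked
    if target.mode == "classification":
        feasible = [kv for kv in ranked if kv[1][0] < CLASS_PENALTY]
    top = feasible[: params.n_results]
    if not top:
        import warnings

        warnings.warn("no feasible sequence found by the search", stacklevel=2)
    seqs = tuple(s for s, _ in top)
    return DesignResult(
        sequences=seqs,
        predicted=np.array([v[1] for _, v in top]),
        distance_to_reference=np.array([v[2] for _, v in top]),
        fitness=np.array([v[0] for _, v in top]),
        fitness_history=np.array(history),
    )


def brute_force_design(
    est: TrainedEstimator,
    target: DesignTarget,
    R: int | None = None,
    lib: PromoterLibrary | None = None,
    batch: int = 4096,
) -> tuple[str, float]:
    """Exhaustive search oracle over all 4^R sequences (R <= 10).

    Evaluates the same fitness as :func:`design_promoters` on every
    length-R sequence in lexicographic order and returns the global
    optimum; ties keep the lexicographically first sequence.
    """
    R = R if R is not None else len(est.position_labels)
    if R > 10:
        raise SearchSpaceError(
            f"exhaustive design over 4^{R} sequences is not enumerable; R <= 10"
        )
    ref_codes = _reference_codes(target, lib, R)
    lib_seqs = frozenset(lib.sequences) if lib is not None else frozenset()
    best_seq, best_fit = None, np.inf
    it = itertools.product(range(4), repeat=R)
    while True:
        chunk = np.array(list(itertools.islice(it, batch)), dtype=np.int8)
        if chunk.size == 0:
            break
        fitness, _, _ = evaluate_fitness(est, chunk, target, ref_codes, lib_seqs)
        i = int(np.argmin(fitness))  # first minimum = lexicographic tie-break
        if fitness[i] < best_fit:
            best_fit = float(fitness[i])
            best_seq = "".join(NUCLEOTIDES[b] for b in chunk[i])
    return best_seq, best_fit
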