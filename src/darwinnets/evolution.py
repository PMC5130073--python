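"""Single-population evolutionary dynamics over attractor networks.

Three experiment families:

* **Selectionist search** — networks are pre-trained with a ladder of
  "special" patterns of graded fitness whose overlapping attractor basins
  form a route to the optimum; no learning occurs during the run, so search
  can only select among the standing variation of stored patterns.
* **Elitist evolution** — only the best output of each generation survives:
  its μ_I-noisy copies become the next inputs and its μ_T-noisy copies
  retrain ``N_T`` randomly chosen networks, which lets new patterns replicate
  (with variation) through the population's memories.
* **Elimination of the worst** — one output is mutated per generation and
  replaces the pool's worst member only on strict fitness improvement; used
  with a periodically alternating environment to probe long-term memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .landscapes import EnvironmentSchedule, SinglePeakLandscape
from .network import AbstractStore, AttractorNetwork
from .patterns import Pattern, VariationParams, mutate, random_pattern

__all__ = [
    "PopulationConfig",
    "GenerationRecord",
    "make_special_ladder",
    "pretrain_networks",
    "selectionist_generation",
    "run_selectionist",
    "elitist_generation",
    "run_elitist",
    "elimination_of_worst_step",
    "run_changing_environment",
    "memory_distance",
    "generations_to_fitness",
]

Unit = AttractorNetwork | AbstractStore


@dataclass
class PopulationConfig:
    """Parameters of a single population of memory units.

    ``N_A`` networks of ``N`` neurons each; ``N_T`` of them are retrained per
    generation (never the same one twice within a generation);
    ``pretrain_count`` random patterns are stored per network before a run
    (keep below the ≈0.25·N palimpsest capacity).
    """

    N_A: int = 20
    N: int = 200
    N_T: int = 1
    variation: VariationParams = field(default_factory=VariationParams)
    pretrain_count: int = 30
    learning_enabled: bool = True
    rule: str = "storkey"

    def __post_init__(self) -> None:
        if not 1 <= self.N_T <= self.N_A:
            raise ValueError(f"N_T must satisfy 1 <= N_T <= N_A, got {self.N_T}")
        if self.pretrain_count > 0.25 * self.N:
            import warnings

            warnings.warn(
                f"pretrain_count={self.pretrain_count} exceeds the palimpsest "
                f"capacity guidance 0.25*N={0.25 * self.N:.0f}",
                stacklevel=2,
            )


@dataclass
class GenerationRecord:
    """Per-generation trajectory entry."""

    generation: int
    best_fitness: float
    mean_fitness: float
    best_pattern: Pattern
    best_producer: int
    memory_distance: int | None = None
    environment: int | None = None


def make_special_ladder(N: int, N_A: int) -> list[Pattern]:
    """Ladder of ``N_A`` special patterns of strictly increasing +1 content.

    Pattern ``k`` (1-based) carries ``round((k−1)·N/(N_A−1))`` leading +1 bits
    and −1 elsewhere: the first rung is uniform −1, the last uniform +1, and
    fitness under the proportion-of-+1 landscape increases with rank.
    """
    if N_A < 2:
        raise ValueError("a ladder needs at least 2 special patterns")
    ladder = []
    for k in range(N_A):
        ones = round(k * N / (N_A - 1))
        p = np.full(N, -1, dtype=np.int8)
        p[:ones] = 1
        ladder.append(p)
    return ladder


def pretrain_networks(
    config: PopulationConfig,
    rng: np.random.Generator,
    special: Sequence[Pattern] | None = None,
) -> list[AttractorNetwork]:
    """Create ``N_A`` networks, each trained on its own random patterns.

    If a ``special`` ladder is given, network ``k`` additionally learns ladder
    pattern ``k`` *last*, so that despite palimpsest forgetting it is reliably
    an attractor.
    """
    nets = []
    for k in range(config.N_A):
        net = AttractorNetwork(config.N, rule=config.rule)
        for _ in range(config.pretrain_count):
            net.learn(random_pattern(config.N, rng))
        if special is not None:
            net.learn(special[k])
        nets.append(net)
    return nets


def pretrain_stores(
    config: PopulationConfig, rng: np.random.Generator, C_fix: int = 30
) -> list[AbstractStore]:
    """Abstract storage units pre-filled with random patterns (FIFO capacity)."""
    stores = []
    for _ in range(config.N_A):
        s = AbstractStore(C_fix, mu_O=config.variation.mu_O)
        for _ in range(config.pretrain_count):
            s.store(random_pattern(config.N, rng))
        stores.append(s)
    return stores


def _learn(unit: Unit, p: Pattern) -> None:
    if isinstance(unit, AbstractStore):
        unit.store(p)
    else:
        unit.learn(p)


def _best_index(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Argmax with uniform random tie-breaking."""
    best = np.flatnonzero(fitnesses == fitnesses.max())
    return int(best[rng.integers(best.size)])


def memory_distance(
    units: Sequence[Unit], best_output: Pattern, producer: int,
    match_complement: bool = False,
) -> int | None:
    """Hamming distance from ``best_output`` to the producing unit's nearest memory.

    ``None`` if the producer has no training history (logged as missing).
    """
    unit = units[producer]
    if not unit.history:
        return None
    return unit.memory_distance(best_output, match_complement=match_complement)


def selectionist_generation(
    nets: Sequence[Unit],
    inputs: Sequence[Pattern],
    land: SinglePeakLandscape,
    mu_I: float,
    rng: np.random.Generator,
) -> tuple[GenerationRecord, list[Pattern]]:
    """One generation of pure selection (no learning).

    Every unit recalls from its input; outputs are pooled; the single fittest
    output ``O_best`` is selected (ties uniformly at random) and its
    independent μ_I-noisy copies become the next inputs of all units.
    """
    outputs = [net.recall(inp, rng) for net, inp in zip(nets, inputs)]
    fit = np.array([land.fitness(o) for o in outputs])
    b = _best_index(fit, rng)
    record = GenerationRecord(
        generation=-1,
        best_fitness=float(fit[b]),
        mean_fitness=float(fit.mean()),
        best_pattern=outputs[b],
        best_producer=b,
    )
    next_inputs = [mutate(outputs[b], mu_I, rng) for _ in nets]
    return record, next_inputs


def run_selectionist(
    config: PopulationConfig,
    rng: np.random.Generator,
    max_generations: int = 200,
    target_fitness: float = 1.0,
) -> list[GenerationRecord]:
    """Ladder experiment: pre-trained special patterns, selection only.

    The proportion-of-+1 landscape is used (uniform +1 target); network ``k``
    holds ladder rung ``k``.  All units receive the same random input at
    generation 0 and the run stops once the optimum is selected.
    """
    land = SinglePeakLandscape.uniform(config.N)
    ladder = make_special_ladder(config.N, config.N_A)
    nets = pretrain_networks(config, rng, special=ladder)
    start = random_pattern(config.N, rng)
    inputs: list[Pattern] = [start] * config.N_A
    records = []
    for t in range(max_generations):
        rec, inputs = selectionist_generation(
            nets, inputs, land, config.variation.mu_I, rng
        )
        rec.generation = t
        records.append(rec)
        if rec.best_fitness >= target_fitness:
            break
    return records


def elitist_generation(
    units: Sequence[Unit],
    inputs: Sequence[Pattern],
    land: SinglePeakLandscape,
    config: PopulationConfig,
    rng: np.random.Generator,
) -> tuple[GenerationRecord, list[Pattern]]:
    """One generation of elitist evolution.

    Recall all units on their inputs, select the single best output, retrain
    ``N_T`` distinct randomly chosen units each on an independent μ_T-noisy
    copy of it, and hand independent μ_I-noisy copies to every unit as the
    next input.
    """
    if config.N_T > len(units):
        raise ValueError("cannot retrain more units than the population holds")
    outputs = [u.recall(inp, rng) for u, inp in zip(units, inputs)]
    fit = np.array([land.fitness(o) for o in outputs])
    b = _best_index(fit, rng)
    best = outputs[b]
    if config.learning_enabled:
        chosen = rng.choice(len(units), size=config.N_T, replace=False)
        for k in chosen:
            _learn(units[k], mutate(best, config.variation.mu_T, rng))
    record = GenerationRecord(
        generation=-1,
        best_fitness=float(fit[b]),
        mean_fitness=float(fit.mean()),
        best_pattern=best,
        best_producer=b,
        memory_distance=memory_distance(units, best, b),
    )
    next_inputs = [mutate(best, config.variation.mu_I, rng) for _ in units]
    return record, next_inputs


def run_elitist(
    config: PopulationConfig,
    rng: np.random.Generator,
    max_generations: int = 5000,
    target_fitness: float = 1.0,
    land: SinglePeakLandscape | None = None,
    units: Sequence[Unit] | None = None,
    C_fix: int = 30,
    abstract: bool = False,
) -> list[GenerationRecord]:
    """Elitist evolutionary search toward a single-peak target.

    Units are pre-trained on random patterns only; the run starts from a
    shared random input and stops when the best output reaches
    ``target_fitness`` or at the generation cap.  With ``abstract=True`` the
    population consists of nearest-prototype storage units instead of
    attractor networks (the simplified comparison model).
    """
    if land is None:
        land = SinglePeakLandscape.uniform(config.N)
    if units is None:
        units = (
            pretrain_stores(config, rng, C_fix=C_fix)
            if abstract
            else pretrain_networks(config, rng)
        )
    start = random_pattern(config.N, rng)
    inputs: list[Pattern] = [start] * config.N_A
    records = []
    for t in range(max_generations):
        rec, inputs = elitist_generation(units, inputs, land, config, rng)
        rec.generation = t
        records.append(rec)
        if rec.best_fitness >= target_fitness:
            break
    return records


def elimination_of_worst_step(
    pool: list[Pattern],
    units: Sequence[Unit],
    land: SinglePeakLandscape,
    mu_R: float,
    N_T: int,
    rng: np.random.Generator,
    learning: bool = True,
) -> list[Pattern]:
    """One elimination-of-the-worst update of an output pool (in place).

    A uniformly chosen pool member is mutated at per-bit rate ``mu_R``; only
    if the mutant is strictly fitter than the worst pool member does it
    replace it, in which case the superior mutant also trains ``N_T``
    distinct units (when learning is on).
    """
    fit = np.array([land.fitness(p) for p in pool])
    mutant = mutate(pool[rng.integers(len(pool))], mu_R, rng)
    mfit = land.fitness(mutant)
    worst = int(fit.argmin())
    if mfit > fit[worst]:
        pool[worst] = mutant
        if learning:
            for k in rng.choice(len(units), size=N_T, replace=False):
                _learn(units[k], mutant)
    return pool


def run_changing_environment(
    config: PopulationConfig,
    sched: EnvironmentSchedule,
    rng: np.random.Generator,
    n_generations: int,
    wipe_memory_at_nolearn: bool = False,
    progress: Callable[[int], None] | None = None,
) -> list[GenerationRecord]:
    """Elimination-of-worst dynamics under a periodically alternating target.

    While learning is enabled (``t < T_nolearn``) the output pool is carried
    between generations (shuffled into the next inputs).  Afterwards learning
    stops and, at every environment switch, inputs are reset to fresh random
    patterns so high fitness can only come from recalling a stored optimum.

    ``wipe_memory_at_nolearn`` is an ablation: erase all network memory at the
    moment learning stops, which should destroy the immediate recovery.
    """
    units = pretrain_networks(config, rng)
    inputs = [random_pattern(config.N, rng) for _ in range(config.N_A)]
    records = []
    for t in range(n_generations):
        land = sched.active(t)
        learning = sched.learning_enabled(t)
        if wipe_memory_at_nolearn and t == sched.T_nolearn:
            for u in units:
                u.wipe()
        if not learning and sched.is_switch(t):
            inputs = [random_pattern(config.N, rng) for _ in range(config.N_A)]
        outputs = [u.recall(inp, rng) for u, inp in zip(units, inputs)]
        fit = np.array([land.fitness(o) for o in outputs])
        b = _best_index(fit, rng)
        records.append(
            GenerationRecord(
                generation=t,
                best_fitness=float(fit[b]),
                mean_fitness=float(fit.mean()),
                best_pattern=outputs[b],
                best_producer=b,
                memory_distance=memory_distance(units, outputs[b], b),
                environment=sched.environment_index(t),
            )
        )
        pool = elimination_of_worst_step(
            outputs, units, land, config.variation.mu_R, config.N_T, rng,
            learning=learning,
        )
        perm = rng.permutation(config.N_A)
        inputs = [pool[i] for i in perm]
        if progress is not None:
            progress(t)
    return records


def generations_to_fitness(
    records: Sequence[GenerationRecord], threshold: float = 1.0
) -> int | None:
    """First generation whose best fitness reaches ``threshold`` (None if never)."""
    for rec in records:
        if rec.best_fitness >= threshold:
            return rec.generation
    return None
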