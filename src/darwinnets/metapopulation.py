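"""Island-model metapopulation of attractor-network demes on a 2D lattice.

Each deme is a small population of attractor networks with an output pool.
Demes sit on a square lattice with Moore (8-cell) neighbourhoods — toroidal
by default so every deme has exactly eight neighbours.  A deme update draws a
single variation event: with probability ``p_rec`` a two-point recombination
of two pool members (the partner coming from a random neighbouring deme with
probability ``p_migr``), otherwise a μ_R mutation of one member.  The best
resulting candidate replaces the pool's worst member only on strict fitness
improvement, in which case it also retrains ``N_T`` networks of the deme.
Updating every deme once, row-major, constitutes one generation.

Block-separable deceptive landscapes (GBBF) are the intended workload: demes
optimise different blocks semi-independently and the slow migration supplies
the cross-deme variability that recombination needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscapes import GBBFLandscape
from .network import AttractorNetwork
from .patterns import Pattern, mutate, random_pattern, two_point_recombine

__all__ = [
    "MetapopConfig",
    "Deme",
    "Metapopulation",
    "moore_neighbors",
    "deme_update",
    "metapop_generation",
    "run_metapopulation",
]


@dataclass
class MetapopConfig:
    """Metapopulation parameters (defaults: the 10×10-deme GBBF configuration)."""

    side: int = 10
    N_A: int = 10
    N: int = 100
    N_T: int = 5
    p_rec: float = 0.1
    p_migr: float = 0.004
    mu_R: float | None = None  # defaults to 1/N
    pretrain_count: int = 20
    rule: str = "storkey"
    torus: bool = True

    def __post_init__(self) -> None:
        if self.mu_R is None:
            self.mu_R = 1.0 / self.N
        for name in ("p_rec", "p_migr", "mu_R"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability in [0, 1]")
        if not 1 <= self.N_T <= self.N_A:
            raise ValueError("N_T must satisfy 1 <= N_T <= N_A")

    @property
    def N_D(self) -> int:
        return self.side * self.side


def moore_neighbors(
    pos: tuple[int, int], dims: tuple[int, int], torus: bool = True
) -> list[tuple[int, int]]:
    """The up-to-eight lattice cells surrounding ``pos``.

    With ``torus`` the lattice wraps and every cell has exactly eight
    neighbours; otherwise edge and corner cells have five and three.
    """
    r, c = pos
    R, C = dims
    if not (0 <= r < R and 0 <= c < C):
        raise ValueError(f"position {pos} outside lattice {dims}")
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if torus:
                out.append((rr % R, cc % C))
            elif 0 <= rr < R and 0 <= cc < C:
                out.append((rr, cc))
    return out


class Deme:
    """One deme: ``N_A`` networks, their input patterns and output pool."""

    def __init__(self, config: MetapopConfig, rng: np.random.Generator):
        self.networks = []
        for _ in range(config.N_A):
            net = AttractorNetwork(config.N, rule=config.rule)
            for _ in range(config.pretrain_count):
                net.learn(random_pattern(config.N, rng))
            self.networks.append(net)
        self.inputs: list[Pattern] = [
            random_pattern(config.N, rng) for _ in range(config.N_A)
        ]
        self.pool: list[Pattern] = list(self.inputs)
        self.pool_fitness: np.ndarray = np.zeros(config.N_A)


def deme_update(
    deme: Deme,
    neighbor_pools: list[list[Pattern]],
    land: GBBFLandscape,
    config: MetapopConfig,
    rng: np.random.Generator,
) -> float:
    """Update one deme in place; returns the deme's best pool fitness.

    Recall on current inputs fills the output pool, then a single mutation or
    recombination event is applied under elimination-of-the-worst acceptance.
    Both recombinants are evaluated and the better one is the replacement
    candidate.  Migration copies the partner from a neighbour's pool without
    removing it.
    """
    pool = [net.recall(inp, rng) for net, inp in zip(deme.networks, deme.inputs)]
    fit = np.array([land.fitness(p) for p in pool])

    if rng.random() < config.p_rec:
        i = int(rng.integers(len(pool)))
        if rng.random() < config.p_migr and neighbor_pools:
            npool = neighbor_pools[rng.integers(len(neighbor_pools))]
            partner = npool[rng.integers(len(npool))]
        else:
            j = int(rng.integers(len(pool) - 1))
            partner = pool[j if j < i else j + 1]
        c1, c2 = two_point_recombine(pool[i], partner, rng)
        f1, f2 = land.fitness(c1), land.fitness(c2)
        candidate, cfit = (c1, f1) if f1 >= f2 else (c2, f2)
    else:
        candidate = mutate(pool[rng.integers(len(pool))], config.mu_R, rng)
        cfit = land.fitness(candidate)

    worst = int(fit.argmin())
    if cfit > fit[worst]:
        pool[worst] = candidate
        fit[worst] = cfit
        for k in rng.choice(len(deme.networks), size=config.N_T, replace=False):
            deme.networks[k].learn(candidate)

    deme.pool = pool
    deme.pool_fitness = fit
    perm = rng.permutation(len(pool))
    deme.inputs = [pool[i] for i in perm]
    return float(fit.max())


class Metapopulation:
    """A ``side × side`` lattice of demes sharing one landscape."""

    def __init__(self, config: MetapopConfig, rng: np.random.Generator):
        self.config = config
        self.demes = {
            (r, c): Deme(config, rng)
            for r in range(config.side)
            for c in range(config.side)
        }
        self._neigh = {
            pos: moore_neighbors(pos, (config.side, config.side), config.torus)
            for pos in self.demes
        }

    def generation(self, land: GBBFLandscape, rng: np.random.Generator) -> float:
        """Update every deme once (row-major scan); returns the global best fitness."""
        return metapop_generation(self, land, rng)

    def best_pattern(self) -> Pattern:
        best, bfit = None, -np.inf
        for deme in self.demes.values():
            i = int(deme.pool_fitness.argmax())
            if deme.pool_fitness[i] > bfit:
                bfit = float(deme.pool_fitness[i])
                best = deme.pool[i]
        return best


def metapop_generation(
    metapop: Metapopulation, land: GBBFLandscape, rng: np.random.Generator
) -> float:
    """One full generation: every deme updated in turn, row-major."""
    best = -np.inf
    cfg = metapop.config
    for r in range(cfg.side):
        for c in range(cfg.side):
            pos = (r, c)
            pools = [metapop.demes[q].pool for q in metapop._neigh[pos]]
            best = max(best, deme_update(metapop.demes[pos], pools, land, cfg, rng))
    return best


def run_metapopulation(
    config: MetapopConfig,
    land: GBBFLandscape,
    rng: np.random.Generator,
    max_generations: int = 50_000,
    target_fitness: float = 1.0,
    record_every: int = 1,
) -> tuple[list[tuple[int, float]], int | None]:
    """Run the metapopulation until the global optimum or the generation cap.

    Returns ``(trajectory, converged_at)`` where the trajectory holds
    ``(generation, global best relative fitness)`` pairs sampled every
    ``record_every`` generations (plus the final generation) and
    ``converged_at`` is the first generation reaching ``target_fitness``.
    """
    metapop = Metapopulation(config, rng)
    trajectory: list[tuple[int, float]] = []
    converged = None
    for t in range(max_generations):
        best = metapop.generation(land, rng)
        if t % record_every == 0:
            trajectory.append((t, best))
        if best >= target_fitness:
            converged = t
            if trajectory[-1][0] != t:
                trajectory.append((t, best))
            break
    return trajectory, converged
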