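"""Fitness landscapes over ±1 patterns.

Three landscape families drive the experiments:

* **Single-peak**: relative Hamming similarity to a fixed target pattern.
  With a uniform +1 target this is simply the proportion of +1 bits.
* **Alternating environment**: a schedule that swaps between two single-peak
  landscapes (uniform +1 and uniform −1 targets) every ``T_E`` generations.
* **General building-block fitness (GBBF)**: the pattern is partitioned into
  ``B`` blocks of length ``P`` (``N = P·B``); each block scores ``w_j > 1`` on
  exactly matching target subsequence ``t_j`` and ``1/(1 + d)`` otherwise,
  where ``d`` is the Hamming distance to the target.  Blocks contribute
  independently, which makes the landscape deceptive (near-miss blocks score
  almost nothing) yet separable, favouring metapopulation search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import Pattern, as_pattern, hamming_distance, relative_similarity

__all__ = [
    "SinglePeakLandscape",
    "GBBFLandscape",
    "EnvironmentSchedule",
    "single_peak_fitness",
    "block_contribution",
    "gbbf_fitness",
    "make_test_landscape",
    "active_target",
]


@dataclass(frozen=True)
class SinglePeakLandscape:
    """Fitness = relative Hamming similarity to ``target`` (1.0 at the peak)."""

    target: Pattern

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", as_pattern(self.target))

    @property
    def N(self) -> int:
        return self.target.shape[0]

    def fitness(self, p: Pattern) -> float:
        return relative_similarity(p, self.target)

    @classmethod
    def uniform(cls, N: int, sign: int = 1) -> "SinglePeakLandscape":
        return cls(np.full(N, sign, dtype=np.int8))


def single_peak_fitness(p: Pattern, land: SinglePeakLandscape) -> float:
    """Relative Hamming similarity of ``p`` to the landscape target."""
    return land.fitness(p)


def block_contribution(g: Pattern, t_j: Pattern, w_j: float) -> float:
    """Score of one block against one target: ``w_j`` on an exact match, else ``1/(1+d)``."""
    d = hamming_distance(np.asarray(g, dtype=np.int8), np.asarray(t_j, dtype=np.int8))
    return float(w_j) if d == 0 else 1.0 / (1.0 + d)


@dataclass
class GBBFLandscape:
    """Block-structured deceptive fitness function.

    Parameters
    ----------
    N, P:
        Pattern length and block length; ``B = N // P`` blocks.
    targets:
        The ``L`` target subsequences of length ``P``, shared by every block.
    weights:
        Subfitness values ``w_j > 1``, one per target.
    global_optimum:
        The pattern used to normalise: relative fitness is raw fitness divided
        by the raw fitness of this pattern, so it scores exactly 1.
    """

    N: int
    P: int
    targets: list[Pattern]
    weights: list[float]
    global_optimum: Pattern | None = None
    _norm: float = field(init=False, repr=False, default=1.0)

    def __post_init__(self) -> None:
        if self.P < 1 or self.N < 1 or self.N % self.P != 0:
            raise ValueError(f"block length {self.P} must divide pattern length {self.N}")
        self.targets = [as_pattern(t) for t in self.targets]
        if any(t.shape[0] != self.P for t in self.targets):
            raise ValueError("every target must have the block length P")
        if len(self.weights) != len(self.targets):
            raise ValueError("one subfitness weight per target is required")
        if any(w <= 1.0 for w in self.weights):
            raise ValueError("subfitness values must exceed 1")
        self._weights = np.asarray(self.weights, dtype=np.float64)
        # targets as (L, P) matrix for vectorised per-block distances
        self._tmat = np.stack(self.targets).astype(np.int8)
        if self.global_optimum is not None:
            self.global_optimum = as_pattern(self.global_optimum)
            self._norm = self.raw_fitness(self.global_optimum)

    @property
    def B(self) -> int:
        return self.N // self.P

    def raw_fitness(self, G: Pattern) -> float:
        """Unnormalised ``F(G) = Σ_blocks Σ_targets c(g_i, t_j)``."""
        G = np.asarray(G, dtype=np.int8)
        if G.shape != (self.N,):
            raise ValueError(f"pattern length {G.shape} does not match N={self.N}")
        blocks = G.reshape(self.B, self.P)
        # d[i, j] = Hamming distance of block i to target j
        d = np.count_nonzero(blocks[:, None, :] != self._tmat[None, :, :], axis=2)
        c = 1.0 / (1.0 + d)
        c = np.where(d == 0, self._weights[None, :], c)
        return float(c.sum())

    def fitness(self, G: Pattern) -> float:
        """Relative fitness, normalised so the global optimum scores 1."""
        return self.raw_fitness(G) / self._norm

    def to_dict(self) -> dict:
        """Config-format description (targets as '+'/'-' strings)."""
        from .patterns import pattern_to_string

        d = {
            "N": self.N,
            "P": self.P,
            "targets": [pattern_to_string(t) for t in self.targets],
            "weights": [float(w) for w in self.weights],
        }
        if self.global_optimum is not None:
            d["global_optimum"] = pattern_to_string(self.global_optimum)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GBBFLandscape":
        from .patterns import pattern_from_string

        return cls(
            N=int(d["N"]),
            P=int(d["P"]),
            targets=[pattern_from_string(t) for t in d["targets"]],
            weights=list(d["weights"]),
            global_optimum=(
                pattern_from_string(d["global_optimum"])
                if d.get("global_optimum") is not None
                else None
            ),
        )


def gbbf_fitness(G: Pattern, land: GBBFLandscape) -> float:
    """Relative building-block fitness of ``G`` under ``land``."""
    return land.fitness(G)


def make_test_landscape(
    N: int, P: int = 10, w1: float = 10.0, w2: float = 9.0
) -> GBBFLandscape:
    """The two-target test landscape: uniform +1 vs the deceptive alternating block.

    Per block, target ``T1`` is the uniform +1 subsequence (weight ``w1``) and
    ``T2`` alternates −1, +1 (weight ``w2 < w1``), making ``T2`` a deceptive
    local optimum of every block while the uniform +1 pattern is the unique
    global optimum.  Fitness is normalised to 1 at the global optimum.
    """
    if P % 2 != 0:
        raise ValueError("block length P must be even for the alternating target")
    if N % P != 0:
        raise ValueError(f"block length {P} must divide pattern length {N}")
    if not w1 > w2 > 1.0:
        raise ValueError("weights must satisfy w1 > w2 > 1")
    T1 = np.ones(P, dtype=np.int8)
    T2 = np.tile(np.array([-1, 1], dtype=np.int8), P // 2)
    return GBBFLandscape(
        N=N,
        P=P,
        targets=[T1, T2],
        weights=[w1, w2],
        global_optimum=np.ones(N, dtype=np.int8),
    )


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Alternation between two single-peak environments every ``T_E`` generations.

    ``E1`` (uniform +1 target) is active on even periods, ``E2`` (uniform −1)
    on odd periods.  After generation ``T_nolearn`` learning is disabled and
    inputs are reset to fresh random patterns at every environment switch.
    """

    N: int
    T_E: int = 2000
    T_nolearn: int = 12000

    def __post_init__(self) -> None:
        if self.T_E < 1:
            raise ValueError("period length T_E must be >= 1")

    def period_index(self, t: int) -> int:
        return t // self.T_E

    def environment_index(self, t: int) -> int:
        """0 for E1 (uniform +1), 1 for E2 (uniform −1)."""
        return self.period_index(t) % 2

    def active(self, t: int) -> SinglePeakLandscape:
        if t < 0:
            raise ValueError("generation index must be >= 0")
        sign = 1 if self.environment_index(t) == 0 else -1
        return SinglePeakLandscape.uniform(self.N, sign)

    def is_switch(self, t: int) -> bool:
        return t > 0 and t % self.T_E == 0

    def learning_enabled(self, t: int) -> bool:
        return t < self.T_nolearn


def active_target(sched: EnvironmentSchedule, t: int) -> SinglePeakLandscape:
    """The single-peak landscape in force at generation ``t``."""
    return sched.active(t)
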