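"""Binary recurrent attractor networks with palimpsest learning.

The network is a fully connected Hopfield-type memory of ``N`` binary (±1)
neurons with a symmetric, zero-diagonal weight matrix.  Two one-shot, local,
incremental learning rules are provided:

* the Hebbian **covariance** rule, ``w_ij ← w_ij + ξ_i ξ_j / N``, with
  capacity ≈ 0.14·N and catastrophic forgetting beyond it;
* the **Storkey** palimpsest rule, which subtracts local-field cross terms so
  that sequential training gracefully overwrites the oldest memories, with a
  palimpsest capacity ≈ 0.25·N.

Recall is asynchronous: neurons update one at a time in a fresh random order
each sweep, a neuron firing (+1) exactly when its local field is strictly
positive.  With a symmetric zero-diagonal weight matrix this dynamics descends
an energy function and always settles in a fixed point.

:class:`AbstractStore` is the simplified comparison model: a FIFO store of at
most ``C_fix`` patterns that returns the nearest stored pattern (plus per-bit
noise) instead of running attractor dynamics.
"""

from __future__ import annotations

from collections import deque
from typing import Deque, Iterable, NamedTuple

import numpy as np
from numba import njit

from .patterns import Pattern, mutate

__all__ = ["AttractorNetwork", "AbstractStore", "RecallResult"]

_SEED_MAX = 2**31 - 1


@njit(cache=True)
def _recall_async(W, x, max_sweeps, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    N = x.shape[0]
    order = np.arange(N)
    # local fields maintained incrementally: updating them only on a flip
    # makes settled sweeps O(N) instead of O(N^2)
    h = W @ x
    sweeps = 0
    for _ in range(max_sweeps):
        np.random.shuffle(order)
        changed = False
        for k in range(N):
            i = order[k]
            new = 1.0 if h[i] > 0.0 else -1.0
            if new != x[i]:
                delta = new - x[i]
                x[i] = new
                for j in range(N):
                    h[j] += W[j, i] * delta
                changed = True
        sweeps += 1
        if not changed:
            return sweeps, True
    return sweeps, False


class RecallResult(NamedTuple):
    pattern: Pattern
    converged: bool
    sweeps: int


class AttractorNetwork:
    """A binary attractor network of ``N`` neurons.

    Parameters
    ----------
    N:
        Number of neurons (= pattern length).
    rule:
        Default learning rule used by :meth:`learn`, ``"storkey"`` or
        ``"covariance"``.

    Notes
    -----
    The training ``history`` is pure bookkeeping for the memory-distance
    diagnostic and spuriousness tests; it never enters the dynamics.
    """

    def __init__(self, N: int, rule: str = "storkey"):
        if N < 1:
            raise ValueError(f"network size must be >= 1, got {N}")
        if rule not in ("storkey", "covariance"):
            raise ValueError(f"unknown learning rule {rule!r}")
        self.N = int(N)
        self.rule = rule
        self.W = np.zeros((N, N), dtype=np.float64)
        self.history: list[Pattern] = []

    # ------------------------------------------------------------------ learning

    def _check(self, xi: Pattern) -> np.ndarray:
        xi = np.asarray(xi)
        if xi.shape != (self.N,):
            raise ValueError(
                f"pattern length {xi.shape} does not match network size {self.N}"
            )
        return xi.astype(np.float64)

    def covariance_learn(self, xi: Pattern) -> "AttractorNetwork":
        """Hebbian covariance update ``w_ij += ξ_i ξ_j / N`` (zero diagonal)."""
        x = self._check(xi)
        self.W += np.outer(x, x) / self.N
        np.fill_diagonal(self.W, 0.0)
        self.history.append(np.asarray(xi, dtype=np.int8).copy())
        return self

    def storkey_learn(self, xi: Pattern) -> "AttractorNetwork":
        """Storkey palimpsest update.

        Uses the local field of the incoming pattern under the *pre-update*
        weights, ``h_i = Σ_k w_ik ξ_k``, and applies
        ``w_ij += (ξ_i ξ_j − ξ_i h_j − h_i ξ_j) / N`` to every off-diagonal
        weight in one shot.
        """
        x = self._check(xi)
        h = self.W @ x
        self.W += (np.outer(x, x) - np.outer(x, h) - np.outer(h, x)) / self.N
        np.fill_diagonal(self.W, 0.0)
        self.history.append(np.asarray(xi, dtype=np.int8).copy())
        return self

    def learn(self, xi: Pattern) -> "AttractorNetwork":
        """Train one pattern with the network's configured rule."""
        if self.rule == "storkey":
            return self.storkey_learn(xi)
        return self.covariance_learn(xi)

    def wipe(self) -> "AttractorNetwork":
        """Erase all memory: zero the weights and clear the history."""
        self.W[:] = 0.0
        self.history.clear()
        return self

    def save(self, path) -> None:
        """Dump weights, rule and training history to an ``.npz`` archive."""
        hist = (
            np.stack(self.history)
            if self.history
            else np.empty((0, self.N), dtype=np.int8)
        )
        np.savez_compressed(path, W=self.W, history=hist, rule=np.str_(self.rule))

    @classmethod
    def load(cls, path) -> "AttractorNetwork":
        """Restore a network from :meth:`save` output."""
        data = np.load(path, allow_pickle=False)
        net = cls(data["W"].shape[0], rule=str(data["rule"]))
        net.W = data["W"].astype(np.float64)
        net.history = [row.copy() for row in data["history"].astype(np.int8)]
        return net

    # ------------------------------------------------------------------- recall

    def recall_full(
        self, cue: Pattern, rng: np.random.Generator, max_sweeps: int = 100
    ) -> RecallResult:
        """Asynchronous recall from ``cue`` with convergence diagnostics.

        The state is initialised to the cue; each sweep updates every neuron
        once in a fresh uniformly random order (the only stochasticity of
        recall); the dynamics stop at the first sweep with no state change or
        after ``max_sweeps`` sweeps.
        """
        if max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        x = self._check(cue)
        sweeps, converged = _recall_async(
            self.W, x, max_sweeps, int(rng.integers(_SEED_MAX))
        )
        return RecallResult(x.astype(np.int8), bool(converged), int(sweeps))

    def recall(
        self, cue: Pattern, rng: np.random.Generator, max_sweeps: int = 100
    ) -> Pattern:
        """Asynchronous recall; returns only the settled state."""
        return self.recall_full(cue, rng, max_sweeps).pattern

    def is_fixed_point(self, p: Pattern) -> bool:
        """True iff a single update of every neuron leaves ``p`` unchanged."""
        x = self._check(p)
        h = self.W @ x
        return bool(np.all(np.where(h > 0.0, 1.0, -1.0) == x))

    # -------------------------------------------------------------- diagnostics

    def memory_distance(self, p: Pattern, match_complement: bool = False) -> int:
        """Minimum Hamming distance from ``p`` to any trained pattern.

        With ``match_complement`` the sign-flipped history is considered too
        (a stored pattern's complement is also an attractor of the dynamics).
        """
        if not self.history:
            raise ValueError("memory distance is undefined for an empty history")
        p = np.asarray(p, dtype=np.int8)
        hist = np.stack(self.history)
        d = np.count_nonzero(hist != p[None, :], axis=1)
        if match_complement:
            d = np.minimum(d, np.count_nonzero(-hist != p[None, :], axis=1))
        return int(d.min())

    def is_spurious(
        self, p: Pattern, tol: int = 0, match_complement: bool = False
    ) -> bool:
        """True iff ``p`` lies farther than ``tol`` from every trained pattern."""
        if not self.history:
            return True
        return self.memory_distance(p, match_complement=match_complement) > tol


class AbstractStore:
    """Capacity-bounded prototype store approximating attractor behaviour.

    Holds at most ``C_fix`` patterns first-in-first-out (the palimpsest
    analogue).  Recall returns the stored pattern nearest to the cue in
    Hamming distance — ties broken uniformly at random — with independent
    per-bit output noise ``mu_O``.
    """

    def __init__(self, C_fix: int, mu_O: float = 0.001):
        if C_fix < 1:
            raise ValueError("capacity must be >= 1")
        if not 0.0 <= mu_O <= 1.0:
            raise ValueError("mu_O must lie in [0, 1]")
        self.C_fix = int(C_fix)
        self.mu_O = float(mu_O)
        self.stored: Deque[Pattern] = deque(maxlen=self.C_fix)
        self.history: list[Pattern] = []

    def store(self, p: Pattern) -> "AbstractStore":
        """Append ``p``; beyond capacity the oldest stored pattern is evicted."""
        p = np.asarray(p, dtype=np.int8).copy()
        self.stored.append(p)
        self.history.append(p.copy())
        return self

    def store_all(self, patterns: Iterable[Pattern]) -> "AbstractStore":
        for p in patterns:
            self.store(p)
        return self

    def recall(self, cue: Pattern, rng: np.random.Generator) -> Pattern:
        """Nearest stored pattern to ``cue`` plus per-bit noise ``mu_O``."""
        if not self.stored:
            raise ValueError("cannot recall from an empty store")
        cue = np.asarray(cue, dtype=np.int8)
        prot = np.stack(self.stored)
        if cue.shape[0] != prot.shape[1]:
            raise ValueError("cue length does not match stored pattern length")
        d = np.count_nonzero(prot != cue[None, :], axis=1)
        best = np.flatnonzero(d == d.min())
        winner = prot[best[rng.integers(best.size)]]
        return mutate(winner, self.mu_O, rng)

    def memory_distance(self, p: Pattern, match_complement: bool = False) -> int:
        if not self.history:
            raise ValueError("memory distance is undefined for an empty history")
        p = np.asarray(p, dtype=np.int8)
        hist = np.stack(self.history)
        d = np.count_nonzero(hist != p[None, :], axis=1)
        if match_complement:
            d = np.minimum(d, np.count_nonzero(-hist != p[None, :], axis=1))
        return int(d.min())
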