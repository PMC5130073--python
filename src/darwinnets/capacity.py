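"""Simulation-based storage-capacity estimates for the two learning rules.

Two protocols, matching how each rule is meant to be loaded:

* **Covariance rule** — train ``M`` random patterns jointly, sweep ``M``, and
  report the largest load ``M/N`` at which at least 90% of the trained
  patterns are retrieved (expected ≈ 0.14).
* **Storkey rule** — train ``2N`` random patterns *sequentially* and count
  how many of the most recently trained patterns are still retrieved; the
  count divided by ``N`` is the palimpsest capacity (expected ≈ 0.25).

A pattern counts as *retrieved* when the asynchronous recall dynamics, cued
with the pattern itself, settle within ``tol`` (a bit fraction, default 2%)
of it.  The default is just above the residual error of the theoretical
retrieval state at capacity (overlap ≈ 0.97, i.e. ≈ 1.6% wrong bits), so the
estimate is insensitive to the precise tolerance: beyond capacity retrieval
collapses to ≈ 50% error rather than degrading gradually.  ``tol = 0``
demands an exact fixed point, which instead measures the much smaller
perfect-stability capacity ≈ 1/(2 ln N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import AttractorNetwork
from .patterns import hamming_distance, random_pattern

__all__ = ["CapacityEstimate", "estimate_capacity", "capacity_table"]


@dataclass
class CapacityEstimate:
    rule: str
    N: int
    ratio: float
    per_replicate: list[float]


def _retrieved(net: AttractorNetwork, pattern, tol_bits: float,
               rng: np.random.Generator) -> bool:
    out = net.recall(pattern, rng)
    return hamming_distance(out, pattern) <= tol_bits


def _covariance_net(N: int, patterns: np.ndarray) -> AttractorNetwork:
    net = AttractorNetwork(N, rule="covariance")
    P = patterns.astype(np.float64)
    net.W = P.T @ P / N
    np.fill_diagonal(net.W, 0.0)
    return net


def _covariance_capacity_once(
    N: int, rng: np.random.Generator, loads: np.ndarray, criterion: float,
    tol_bits: float,
) -> float:
    best = 0
    for M in loads:
        pats = np.stack([random_pattern(N, rng) for _ in range(M)])
        net = _covariance_net(N, pats)
        ok = sum(_retrieved(net, p, tol_bits, rng) for p in pats)
        if ok / M >= criterion:
            best = max(best, int(M))
    return best / N


def _storkey_capacity_once(
    N: int, rng: np.random.Generator, n_train: int, tol_bits: float
) -> float:
    net = AttractorNetwork(N, rule="storkey")
    pats = [random_pattern(N, rng) for _ in range(n_train)]
    for p in pats:
        net.storkey_learn(p)
    ok = sum(_retrieved(net, p, tol_bits, rng) for p in pats)
    return ok / N


def estimate_capacity(
    rule: str,
    N: int = 200,
    replicates: int = 20,
    rng: np.random.Generator | None = None,
    criterion: float = 0.9,
    tol: float = 0.02,
    loads: np.ndarray | None = None,
) -> CapacityEstimate:
    """Monte-Carlo capacity ratio of a learning rule at network size ``N``.

    For the covariance rule, ``loads`` is the sweep of joint pattern counts
    ``M`` (default 2 … 0.25·N) and ``criterion`` the required retrieved
    fraction.  For the Storkey rule, 2·N patterns are trained sequentially
    per replicate and the surviving retrievable patterns are counted.
    ``tol`` is the retrieval tolerance as a fraction of ``N`` (0 for the
    exact-fixed-point variant).
    """
    if rule not in ("covariance", "storkey"):
        raise ValueError(f"unknown learning rule {rule!r}")
    if N < 50 or replicates < 1:
        raise ValueError("capacity estimation needs N >= 50 and replicates >= 1")
    if not 0.0 <= tol < 0.5:
        raise ValueError("tol is a bit fraction in [0, 0.5)")
    if rng is None:
        rng = np.random.default_rng()
    if loads is None:
        loads = np.arange(2, int(0.25 * N) + 1)
    tol_bits = tol * N
    values = []
    for _ in range(replicates):
        if rule == "covariance":
            values.append(
                _covariance_capacity_once(N, rng, loads, criterion, tol_bits)
            )
        else:
            values.append(_storkey_capacity_once(N, rng, 2 * N, tol_bits))
    return CapacityEstimate(rule, N, float(np.mean(values)), values)


def capacity_table(
    rule: str,
    N: int = 200,
    replicates: int = 10,
    rng: np.random.Generator | None = None,
    loads: np.ndarray | None = None,
    tol: float = 0.02,
) -> list[dict]:
    """Load-versus-retrieval table: fraction of patterns retrieved at each load.

    For the covariance rule the ``M`` patterns are trained jointly; for the
    Storkey rule sequentially, scoring the ``M`` most recent of a 2·N-long
    training stream.
    """
    if rng is None:
        rng = np.random.default_rng()
    if loads is None:
        loads = np.arange(5, int(0.3 * N) + 1, max(1, N // 40))
    tol_bits = tol * N
    rows = []
    for M in loads:
        fracs = []
        for _ in range(replicates):
            if rule == "covariance":
                pats = np.stack([random_pattern(N, rng) for _ in range(M)])
                net = _covariance_net(N, pats)
                scored = pats
            else:
                net = AttractorNetwork(N, rule="storkey")
                stream = [random_pattern(N, rng) for _ in range(2 * N)]
                for p in stream:
                    net.storkey_learn(p)
                scored = np.stack(stream[-int(M):])
            ok = sum(_retrieved(net, p, tol_bits, rng) for p in scored)
            fracs.append(ok / len(scored))
        rows.append(
            {"rule": rule, "N": N, "M": int(M), "load": M / N,
             "retrieved_fraction": float(np.mean(fracs))}
        )
    return rows
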