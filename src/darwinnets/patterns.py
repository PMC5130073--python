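"""Binary ±1 patterns and their variation operators.

A pattern is the unit of selection throughout the package: a length-``N``
numpy array of dtype ``int8`` whose entries are exactly −1 or +1, matching the
two states of the binary neurons in the attractor networks.  Variation acts on
patterns through per-bit mutation, two-point recombination and signed mixtures
(the "spurious pattern" construction of associative memories).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Pattern",
    "VariationParams",
    "as_pattern",
    "random_pattern",
    "hamming_distance",
    "relative_similarity",
    "mutate",
    "two_point_recombine",
    "spurious_combine",
    "pattern_to_string",
    "pattern_from_string",
]

#: A pattern is an int8 numpy array over {-1, +1}.
Pattern = np.ndarray


@dataclass(frozen=True)
class VariationParams:
    """Per-bit probabilities of the variation operators.

    Parameters
    ----------
    mu_I:
        Mutation probability applied to input copies of the selected best
        output before redistribution to the networks.
    mu_T:
        Mutation probability applied to training copies of the best output.
    mu_R:
        Mutation rate of the elimination-of-the-worst step (typically 1/N).
    mu_O:
        Output noise of the abstract storage-unit model.
    p_rec:
        Probability that a selection event is a recombination rather than a
        mutation.
    """

    mu_I: float = 0.005
    mu_T: float = 0.01
    mu_R: float = 0.0
    mu_O: float = 0.001
    p_rec: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_I", "mu_T", "mu_R", "mu_O", "p_rec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} is not a probability in [0, 1]")


def as_pattern(bits: Sequence[int] | np.ndarray) -> Pattern:
    """Coerce a sequence to a validated ±1 int8 pattern."""
    arr = np.asarray(bits, dtype=np.int8)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("pattern must be a non-empty 1-D sequence")
    if not np.all(np.abs(arr) == 1):
        raise ValueError("pattern entries must be exactly -1 or +1")
    return arr


def random_pattern(N: int, rng: np.random.Generator) -> Pattern:
    """Draw a uniform random ±1 pattern of length ``N``."""
    if N < 1:
        raise ValueError(f"pattern size must be >= 1, got {N}")
    return (2 * rng.integers(0, 2, size=N, dtype=np.int8) - 1).astype(np.int8)


def pattern_to_string(p: Pattern) -> str:
    """Serialize a pattern as a '+'/'-' string (e.g. ``"++-+"``)."""
    return "".join("+" if b > 0 else "-" for b in as_pattern(p))


def pattern_from_string(s: str) -> Pattern:
    """Parse a '+'/'-' string back into a ±1 pattern."""
    if not s or set(s) - {"+", "-"}:
        raise ValueError(f"pattern string must be non-empty over '+'/'-': {s!r}")
    return np.array([1 if c == "+" else -1 for c in s], dtype=np.int8)


def _check_lengths(a: Pattern, b: Pattern) -> None:
    if a.shape != b.shape:
        raise ValueError(f"pattern length mismatch: {a.shape[0]} vs {b.shape[0]}")


def hamming_distance(a: Pattern, b: Pattern) -> int:
    """Number of positions at which two equal-length patterns differ."""
    _check_lengths(a, b)
    return int(np.count_nonzero(a != b))


def relative_similarity(a: Pattern, b: Pattern) -> float:
    """Per-bit Hamming similarity, ``1 - d(a, b)/N``; 1 iff equal, 0 iff complementary."""
    _check_lengths(a, b)
    return 1.0 - hamming_distance(a, b) / a.shape[0]


def mutate(p: Pattern, mu: float, rng: np.random.Generator) -> Pattern:
    """Return a copy of ``p`` with each bit independently flipped with probability ``mu``."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mutation probability must lie in [0, 1], got {mu}")
    out = p.copy()
    if mu == 0.0:
        return out
    flips = rng.random(p.shape[0]) < mu
    out[flips] = -out[flips]
    return out


def two_point_recombine(
    a: Pattern, b: Pattern, rng: np.random.Generator
) -> tuple[Pattern, Pattern]:
    """Two-point crossover on a linear string.

    Two distinct cut points are drawn uniformly from the ``N + 1`` bit
    boundaries and the segment between them is exchanged, so each position of
    each offspring carries either the ``a`` or the ``b`` allele and the pair
    jointly preserves the multiset of bits at every position.
    """
    _check_lengths(a, b)
    N = a.shape[0]
    lo, hi = np.sort(rng.choice(N + 1, size=2, replace=False))
    c, d = a.copy(), b.copy()
    c[lo:hi], d[lo:hi] = b[lo:hi], a[lo:hi]
    return c, d


def spurious_combine(
    patterns: Sequence[Pattern],
    signs: Sequence[int] | None = None,
    overall_sign: int = 1,
) -> Pattern:
    """Signed mixture of an odd number of patterns.

    Computes ``±sgn(±ξ¹ ± ξ² ... ± ξˢ)`` element-wise.  An odd count makes a
    zero sum impossible, so the output is always a valid ±1 pattern.  These
    mixtures are the spurious attractors of associative memories and act as an
    implicit recombination operator during recall.
    """
    if len(patterns) % 2 == 0 or len(patterns) < 1:
        raise ValueError("spurious mixtures require an odd number of patterns >= 1")
    if signs is None:
        signs = [1] * len(patterns)
    if len(signs) != len(patterns):
        raise ValueError("one sign is required per pattern")
    if any(s not in (-1, 1) for s in signs) or overall_sign not in (-1, 1):
        raise ValueError("signs must be -1 or +1")
    stack = np.stack([np.asarray(p, dtype=np.int64) for p in patterns])
    if not np.all(np.abs(stack) == 1):
        raise ValueError("pattern entries must be exactly -1 or +1")
    if len({p.shape for p in patterns}) != 1:
        raise ValueError("patterns must share a common length")
    total = np.asarray(signs, dtype=np.int64) @ stack
    return (overall_sign * np.sign(total)).astype(np.int8)
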