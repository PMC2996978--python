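"""Per-gene sample partitions and the tolerance matching rule.

A gene "selects for" the *s* samples in which it is most highly expressed.
Two genes induce the same partition on the samples, up to tolerance *t*,
when their top-*s* sample sets differ by at most *t* elements.  Because both
sets have exactly *s* members the overlap deficit ``s - |A ∩ B|`` equals
``|A \\ B|`` and ``|B \\ A|`` and is half the symmetric difference, so a
single integer captures the mismatch.

The chance that two unrelated genes pass the matching rule is the tail of a
hypergeometric distribution (two independent uniform size-*s* subsets of *n*
samples overlapping in at least *k* elements), which bounds the number of
spurious matches expected in an enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "TopSampleSet",
    "MatchParams",
    "rank_order",
    "induce_partition",
    "mismatch",
    "is_match",
    "overlap_tail_pvalue",
]


@dataclass(frozen=True)
class TopSampleSet:
    """The size-``s`` sample subset a gene selects for.

    Attributes
    ----------
    probe_id : str
        Identifier of the probe (row) that induced the set.
    s : int
        Partition size.
    samples : frozenset of int
        The ``s`` sample indices (0-based) with the largest expression.
    rank_order : tuple of int
        The same indices ordered by descending expression, ties broken by
        ascending sample index.
    """

    probe_id: str
    s: int
    samples: frozenset = field(repr=False)
    rank_order: tuple = ()

    def __post_init__(self) -> None:
        if len(self.samples) != self.s:
            raise ValueError(
                f"samples must have exactly s={self.s} members, "
                f"got {len(self.samples)}"
            )
        if self.rank_order and set(self.rank_order) != set(self.samples):
            raise ValueError("rank_order must be a permutation of samples")


@dataclass(frozen=True)
class MatchParams:
    """Partition size ``s`` and tolerance ``t`` controlling the match rule."""

    s: int
    t: int

    def __post_init__(self) -> None:
        if self.t < 0 or self.t >= self.s:
            raise ValueError(f"require 0 <= t < s, got s={self.s}, t={self.t}")


def rank_order(values: np.ndarray) -> np.ndarray:
    """Sample indices ordered by descending value, ties by ascending index.

    The full order is a fixed permutation of ``0..n-1``; every top-``s`` set
    is a prefix of it, which makes top sets nested in ``s``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be a 1-d vector")
    if np.isnan(values).any():
        raise ValueError("values contain missing entries; impute first")
    # lexsort: last key is primary -> descending value, then ascending index
    return np.lexsort((np.arange(values.shape[0]), -values))


def induce_partition(values: np.ndarray, s: int, probe_id: str = "") -> TopSampleSet:
    """Top-``s`` sample set induced by one gene's expression vector."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if not 1 <= s <= n:
        raise ValueError(f"s must be in [1, {n}], got {s}")
    order = rank_order(values)[:s]
    return TopSampleSet(
        probe_id=probe_id,
        s=s,
        samples=frozenset(int(i) for i in order),
        rank_order=tuple(int(i) for i in order),
    )


def mismatch(a: TopSampleSet, b: TopSampleSet) -> int:
    """Overlap deficit ``s - |a ∩ b|`` between two equal-size top sets."""
    if a.s != b.s:
        raise ValueError(f"partition sizes differ: {a.s} != {b.s}")
    return a.s - len(a.samples & b.samples)


def is_match(a: TopSampleSet, b: TopSampleSet, t: int) -> bool:
    """Whether two genes induce the same partition at tolerance ``t``."""
    if t < 0:
        raise ValueError("tolerance t must be >= 0")
    return mismatch(a, b) <= t


def overlap_tail_pvalue(n: int, s: int, k: int) -> float:
    """P(two independent uniform size-``s`` subsets of ``n`` overlap >= ``k``).

    Conditioning on one subset, the overlap of the other is hypergeometric
    with population ``n``, ``s`` successes and ``s`` draws, so the value is
    ``sum_{i=k..s} C(s,i) C(n-s, s-i) / C(n,s)``.  Evaluated through the
    survival function, which is computed stably for large ``n``.
    """
    if not (0 <= k <= s <= n):
        raise ValueError(f"require 0 <= k <= s <= n, got n={n}, s={s}, k={k}")
    return float(np.clip(hypergeom.sf(k - 1, n, s, s), 0.0, 1.0))
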