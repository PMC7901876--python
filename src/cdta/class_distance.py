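"""Kullback-Leibler separation between latent classes, per item.

Each item induces a Bernoulli response distribution under every latent
class. The KL divergence between the distributions under classes ``u`` and
``v`` measures how well the item separates those two classes; it is
asymmetric, so both directions of every pair are kept. Stacking the
off-diagonal entries of every item's T x T distance matrix column-wise
yields the pair-by-item matrix ``V`` that the maximin assembly program
operates on.

Two pair sets are supported:

* ``FULL`` — all ``T(T-1)`` ordered off-diagonal pairs, in row-major order
  (``u`` outer, ``v`` inner, diagonal skipped).
* ``SIMPLIFIED`` — only the ``T*K`` ordered pairs of patterns at Hamming
  distance 1 (the nearest-neighbour mastery patterns), both directions.
  These are the hardest pairs to separate; dropping the rest shrinks the
  optimization with little loss of classification accuracy.

Natural logarithms are used throughout. A fixed base only rescales every
coefficient of the assembly program and cannot change which test is
optimal, but fixing it makes distance values reproducible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .cdm_core import PROB_CLIP, LatentClassSpace, ProbabilityTable

__all__ = [
    "PairMode",
    "PairIndex",
    "StackedDistanceMatrix",
    "kl_distance",
    "item_distance_matrix",
    "full_pairs",
    "minimal_pairs",
    "stack_distances",
]

#: FULL mode has T(T-1) rows; above this K an explicit override is required.
FULL_MODE_MAX_K = 6


class PairMode(str, enum.Enum):
    FULL = "FULL"
    SIMPLIFIED = "SIMPLIFIED"

    @classmethod
    def coerce(cls, value: "PairMode | str") -> "PairMode":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


@dataclass(frozen=True)
class PairIndex:
    """Ordered class-index pairs (u, v), u != v, defining the rows of V."""

    pairs: np.ndarray = field(repr=False)  # (R, 2) int array
    mode: PairMode

    @property
    def R(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class StackedDistanceMatrix:
    """Pair-by-item KL separation matrix ``V`` with its pair index.

    ``V[t, j]`` is the KL divergence between item ``j``'s response
    distributions under the two classes of pair ``t``.
    """

    V: np.ndarray = field(repr=False)
    index: PairIndex
    source: ProbabilityTable = field(repr=False)

    @property
    def n_items(self) -> int:
        return self.V.shape[1]

    @property
    def R(self) -> int:
        return self.V.shape[0]


def kl_distance(p_u, p_v):
    """Bernoulli KL divergence ``D(p_u || p_v)`` in nats.

    ``p_u log(p_u/p_v) + (1-p_u) log((1-p_u)/(1-p_v))``; nonnegative, zero
    iff the two success probabilities coincide, and asymmetric in general.
    Accepts scalars or broadcastable arrays.
    """
    p_u = np.asarray(p_u, dtype=float)
    p_v = np.asarray(p_v, dtype=float)
    if ((p_u < 0) | (p_u > 1)).any() or ((p_v < 0) | (p_v > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pu = np.clip(p_u, PROB_CLIP, 1 - PROB_CLIP)
    pv = np.clip(p_v, PROB_CLIP, 1 - PROB_CLIP)
    out = pu * np.log(pu / pv) + (1 - pu) * np.log((1 - pu) / (1 - pv))
    # exact zero for identical inputs, immune to rounding in the log terms
    out = np.where(p_u == p_v, 0.0, out)
    return out if out.ndim else float(out)


def item_distance_matrix(item_column: np.ndarray) -> np.ndarray:
    """T x T matrix of pairwise KL distances for one item's class probabilities."""
    p = np.asarray(item_column, dtype=float)
    if p.ndim != 1:
        raise ValueError("item_column must be a 1-D vector of class probabilities")
    return kl_distance(p[:, None], p[None, :])


def full_pairs(space: LatentClassSpace) -> PairIndex:
    """All T(T-1) ordered off-diagonal pairs, row-major with diagonal removed."""
    T = space.T
    u, v = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
    keep = u != v
    pairs = np.column_stack([u[keep], v[keep]])
    return PairIndex(pairs=pairs, mode=PairMode.FULL)


def minimal_pairs(space: LatentClassSpace) -> PairIndex:
    """Ordered pairs of patterns at Hamming distance exactly 1 (T*K of them).

    Every pattern has K nearest neighbours (flip one attribute); both
    directions of each pair are kept because KL is asymmetric. Row order is
    the FULL row-major order restricted to these pairs.
    """
    T = space.T
    u, v = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
    keep = u != v
    uu, vv = u[keep], v[keep]
    hamming = (space.patterns[uu] != space.patterns[vv]).sum(axis=1)
    sel = hamming == 1
    pairs = np.column_stack([uu[sel], vv[sel]])
    return PairIndex(pairs=pairs, mode=PairMode.SIMPLIFIED)


def stack_distances(
    table: ProbabilityTable,
    mode: PairMode | str = PairMode.SIMPLIFIED,
    space: LatentClassSpace | None = None,
    allow_large_full: bool = False,
) -> StackedDistanceMatrix:
    """Build the stacked pair-by-item KL matrix ``V`` for an item bank.

    Parameters
    ----------
    table:
        Class-by-item probability table over the full latent-class space.
    mode:
        ``FULL`` (all ordered pairs) or ``SIMPLIFIED`` (Hamming-1 pairs).
    space:
        The latent-class space; inferred from the table's row count when
        omitted.
    allow_large_full:
        FULL mode with more than ``2**6`` classes produces very tall
        matrices (65,280 rows at K=8); require an explicit opt-in.
    """
    mode = PairMode.coerce(mode)
    if space is None:
        from .cdm_core import enumerate_latent_classes

        K = int(np.log2(table.n_classes))
        if 2**K != table.n_classes:
            raise ValueError("table row count is not a power of two; pass space=")
        space = enumerate_latent_classes(K)
    if mode is PairMode.FULL and space.K > FULL_MODE_MAX_K and not allow_large_full:
        raise ValueError(
            f"FULL mode with K={space.K} creates {space.T * (space.T - 1)} rows; "
            "pass allow_large_full=True to proceed"
        )
    index = full_pairs(space) if mode is PairMode.FULL else minimal_pairs(space)
    P = table.probs  # (T, M)
    pu = P[index.pairs[:, 0], :]
    pv = P[index.pairs[:, 1], :]
    V = kl_distance(pu, pv)
    return StackedDistanceMatrix(V=V, index=index, source=table)
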