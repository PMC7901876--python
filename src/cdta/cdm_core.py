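"""Latent-class space, Q-matrix, item parameters, and CDM response kernels.

Three conjunctive/disjunctive cognitive diagnostic models are supported:

* **DINA** (deterministic input, noisy "and"): an examinee answers correctly
  with probability ``1 - s_j`` when they master *every* attribute the item
  measures, and with guessing probability ``g_j`` otherwise.
* **DINO** (deterministic input, noisy "or"): mastering *any one* measured
  attribute suffices for the high-probability response ``1 - s_j``.
* **R-RUM** (reduced reparameterized unified model): a baseline success
  probability ``pi*_j`` is multiplicatively penalized by ``r*_jk < 1`` for
  each measured attribute the examinee lacks.

The latent-class space is the set of all ``T = 2**K`` binary attribute
patterns. Patterns are kept in binary-integer order with attribute 1 as the
most significant bit, so the index of a pattern is its base-2 value; this
convention is fixed so that class-pair indices are reproducible everywhere
downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Model",
    "QMatrix",
    "ItemParameters",
    "LatentClassSpace",
    "ProbabilityTable",
    "enumerate_latent_classes",
    "ideal_response",
    "response_probability",
    "class_probability_table",
    "PROB_CLIP",
]

#: Probabilities are clamped to [PROB_CLIP, 1 - PROB_CLIP] before logarithms.
#: Under the generating parameter ranges used here clipping is never active;
#: it only guards user-supplied parameter files.
PROB_CLIP = 1e-12

#: Hard ceiling on the attribute count: the class space has 2**K patterns.
MAX_ATTRIBUTES = 12


class Model(str, enum.Enum):
    """Supported cognitive diagnostic models."""

    DINA = "DINA"
    DINO = "DINO"
    RRUM = "RRUM"

    @classmethod
    def coerce(cls, value: "Model | str") -> "Model":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


@dataclass(frozen=True)
class QMatrix:
    """Binary item-by-attribute incidence matrix.

    ``entries[j, k] == 1`` means item ``j`` measures attribute ``k``. Every
    item must measure at least one attribute.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.entries)
        if q.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional (items x attributes)")
        if not np.isin(q, (0, 1)).all():
            bad = np.argwhere(~np.isin(q, (0, 1)))[0]
            raise ValueError(
                f"Q-matrix entries must be 0/1; found {q[tuple(bad)]!r} at "
                f"item {bad[0]}, attribute {bad[1]}"
            )
        if (q.sum(axis=1) == 0).any():
            row = int(np.argmax(q.sum(axis=1) == 0))
            raise ValueError(f"item {row} measures no attribute (all-zero Q row)")
        object.__setattr__(self, "entries", q.astype(np.int8))

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def attributes_per_item(self) -> np.ndarray:
        """Number of attributes measured by each item."""
        return self.entries.sum(axis=1)


@dataclass(frozen=True)
class ItemParameters:
    """Model-tagged per-item parameters.

    DINA/DINO use ``slip`` and ``guess`` vectors; R-RUM uses a ``baseline``
    vector (``pi*``) and an item-by-attribute ``penalty`` matrix (``r*``),
    meaningful only where the Q-matrix has a 1 (other cells are ignored and
    may be NaN).
    """

    model: Model
    slip: np.ndarray | None = None
    guess: np.ndarray | None = None
    baseline: np.ndarray | None = None
    penalty: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model.coerce(self.model))
        if self.model in (Model.DINA, Model.DINO):
            if self.slip is None or self.guess is None:
                raise ValueError(f"{self.model.value} requires slip and guess vectors")
            s = np.asarray(self.slip, dtype=float)
            g = np.asarray(self.guess, dtype=float)
            for name, v in (("slip", s), ("guess", g)):
                if ((v <= 0) | (v >= 1)).any():
                    raise ValueError(f"{name} probabilities must lie in (0, 1)")
            object.__setattr__(self, "slip", s)
            object.__setattr__(self, "guess", g)
        else:
            if self.baseline is None or self.penalty is None:
                raise ValueError("RRUM requires baseline (pi*) and penalty (r*)")
            b = np.asarray(self.baseline, dtype=float)
            r = np.asarray(self.penalty, dtype=float)
            if ((b <= 0) | (b >= 1)).any():
                raise ValueError("baseline probabilities must lie in (0, 1)")
            with np.errstate(invalid="ignore"):
                if ((r <= 0) | (r >= 1)).any():
                    raise ValueError("penalty entries must lie in (0, 1) where defined")
            object.__setattr__(self, "baseline", b)
            object.__setattr__(self, "penalty", r)

    @property
    def n_items(self) -> int:
        if self.model in (Model.DINA, Model.DINO):
            return len(self.slip)
        return len(self.baseline)


@dataclass(frozen=True)
class LatentClassSpace:
    """All ``T = 2**K`` binary attribute patterns in binary-integer order."""

    K: int
    patterns: np.ndarray = field(repr=False)

    @property
    def T(self) -> int:
        return self.patterns.shape[0]

    def pattern_index(self, alphas: np.ndarray) -> np.ndarray:
        """Map binary pattern rows to their class indices (base-2 values)."""
        alphas = np.atleast_2d(np.asarray(alphas))
        weights = 1 << np.arange(self.K - 1, -1, -1)
        return alphas @ weights

    def bitstrings(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.patterns]


@dataclass(frozen=True)
class ProbabilityTable:
    """Correct-response probabilities ``P_j(alpha_c)`` for every class/item.

    ``probs[c, j]`` is the probability that an examinee in latent class
    ``c`` answers item ``j`` correctly. For DINA/DINO the binary ideal
    responses (eta / omega) are kept alongside; R-RUM has no binary ideal
    response, so ``ideal`` is ``None``.
    """

    probs: np.ndarray
    model: Model
    ideal: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]

    @property
    def n_items(self) -> int:
        return self.probs.shape[1]

    def restrict(self, items: np.ndarray) -> "ProbabilityTable":
        """Sub-table for a selection of item indices (e.g. an assembled test)."""
        items = np.asarray(items)
        ideal = None if self.ideal is None else self.ideal[:, items]
        return ProbabilityTable(self.probs[:, items], self.model, ideal)


def enumerate_latent_classes(K: int) -> LatentClassSpace:
    """Enumerate all 2**K attribute mastery patterns.

    Patterns are returned in binary-integer order with attribute 1 as the
    most significant bit: for K=2 the order is (0,0), (0,1), (1,0), (1,1).

    Parameters
    ----------
    K:
        Number of attributes, ``1 <= K <= 12``.
    """
    if not 1 <= K <= MAX_ATTRIBUTES:
        raise ValueError(f"K must be between 1 and {MAX_ATTRIBUTES}, got {K}")
    codes = np.arange(2**K, dtype=np.int64)
    shifts = np.arange(K - 1, -1, -1)
    patterns = ((codes[:, None] >> shifts[None, :]) & 1).astype(np.int8)
    return LatentClassSpace(K=K, patterns=patterns)


def ideal_response(q_row: np.ndarray, alpha: np.ndarray, model: Model | str) -> int:
    """Binary ideal response of pattern ``alpha`` to an item with row ``q_row``.

    DINA: 1 iff every measured attribute is mastered (conjunctive).
    DINO: 1 iff at least one measured attribute is mastered (disjunctive).
    R-RUM has no binary ideal response and is rejected.
    """
    model = Model.coerce(model)
    q = np.asarray(q_row)
    a = np.asarray(alpha)
    if q.shape != a.shape:
        raise ValueError("q_row and alpha must have the same length")
    if model is Model.DINA:
        return int(np.all(a[q == 1] == 1))
    if model is Model.DINO:
        return int(np.any(a[q == 1] == 1))
    raise ValueError("R-RUM has no binary ideal response")


def response_probability(
    q_row: np.ndarray,
    params: ItemParameters,
    alpha: np.ndarray,
    item: int = 0,
) -> float:
    """Correct-response probability of one latent pattern on one item.

    Scalar reference implementation of the three model kernels; the
    vectorized :func:`class_probability_table` must agree with it elementwise.
    """
    model = params.model
    q = np.asarray(q_row)
    a = np.asarray(alpha)
    if model in (Model.DINA, Model.DINO):
        eta = ideal_response(q, a, model)
        s = float(params.slip[item])
        g = float(params.guess[item])
        return (1.0 - s) if eta else g
    # R-RUM: baseline times penalty for every measured-but-unmastered attribute
    p = float(params.baseline[item])
    for k in np.flatnonzero((q == 1) & (a == 0)):
        p *= float(params.penalty[item, k])
    return p


def class_probability_table(
    q: QMatrix, params: ItemParameters, space: LatentClassSpace
) -> ProbabilityTable:
    """Tabulate ``P_j(alpha_c)`` over the full class space (T x M).

    Vectorized; identical values to calling :func:`response_probability`
    per cell. Probabilities are clipped to ``[PROB_CLIP, 1 - PROB_CLIP]``
    so that logarithms downstream are always defined.
    """
    if params.n_items != q.n_items:
        raise ValueError(
            f"parameter count {params.n_items} does not match item count {q.n_items}"
        )
    if space.K != q.n_attributes:
        raise ValueError(
            f"class space has K={space.K} but Q-matrix has {q.n_attributes} attributes"
        )
    qm = q.entries.astype(np.int64)  # (M, K)
    alphas = space.patterns.astype(np.int64)  # (T, K)
    model = params.model
    ideal = None
    if model is Model.DINA:
        # missing[c, j] = number of measured attributes class c lacks on item j
        missing = (1 - alphas) @ qm.T
        ideal = (missing == 0).astype(np.int8)
        probs = np.where(ideal == 1, 1.0 - params.slip, params.guess)
    elif model is Model.DINO:
        mastered = alphas @ qm.T
        ideal = (mastered > 0).astype(np.int8)
        probs = np.where(ideal == 1, 1.0 - params.slip, params.guess)
    else:
        # log-space product over attributes: sum_k (1 - alpha_ck) q_jk log r_jk
        logr = np.log(np.where(qm == 1, params.penalty, 1.0))  # (M, K)
        probs = params.baseline * np.exp((1 - alphas) @ logr.T)
    probs = np.clip(probs, PROB_CLIP, 1.0 - PROB_CLIP)
    return ProbabilityTable(probs=probs, model=model, ideal=ideal)
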