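"""Test assembly: maximin-distance MILP, CDI-greedy, and random baselines.

The maximize-minimum-distance (MMD) assembler selects a fixed-length test
from an item bank so that the smallest inter-class KL separation of the
assembled test is as large as possible, while also rewarding the mean
separation. With ``V`` the pair-by-item distance matrix (R rows), ``x`` the
binary selection vector and ``y`` a free slack scalar, it solves

    minimize    f1.x + f2 * y
    subject to  V x + y >= b,   sum(x) = J,   x binary,   y real

where ``f1_j`` is minus the mean of column ``j`` of ``V`` (so minimizing
maximizes total separation), ``f2 = J * mean(V) > 0`` weights the slack, and
``b_t = J * mean(row t)`` is the bank-average target separation for pair
``t``. At the optimum ``y = max_t (b_t - V_t.x)``, so minimizing ``f2*y``
pushes up the smallest inter-class distance of the selected test.

Optional constraint modes mirror common test-blueprint rules:

* ``NC`` — no constraints beyond the test length.
* ``IC`` — item-count quotas: exactly ``ic_counts[a]`` selected items must
  measure ``a`` attributes, for each quota key ``a``.
* ``AC`` — attribute coverage: every attribute must be measured by at least
  ``ac_min`` selected items.

Two baselines are provided: greedy selection by the cognitive diagnostic
index (CDI) — an inverse-Hamming-weighted mean of an item's pairwise KL
distances — and uniform random selection. All three honor the same
constraint modes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .cdm_core import LatentClassSpace, QMatrix
from .class_distance import StackedDistanceMatrix, full_pairs, kl_distance

__all__ = [
    "ConstraintMode",
    "AssemblyMethod",
    "SolutionStatus",
    "AssemblyProblem",
    "AssemblySolution",
    "build_problem",
    "solve_mmd",
    "cdi_index",
    "cdi_indices",
    "assemble_cdi",
    "assemble_random",
    "DEFAULT_IC_COUNTS_K4",
    "DEFAULT_AC_MIN",
]

#: Item-count quotas for a 20-item test on four attributes: 9 three-attribute,
#: 7 two-attribute, 4 single-attribute items.
DEFAULT_IC_COUNTS_K4 = {1: 4, 2: 7, 3: 9}

#: Minimum per-attribute coverage for AC mode (K=4, J=20 blueprint).
DEFAULT_AC_MIN = 7


class ConstraintMode(str, enum.Enum):
    NC = "NC"
    IC = "IC"
    AC = "AC"

    @classmethod
    def coerce(cls, value: "ConstraintMode | str") -> "ConstraintMode":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


class AssemblyMethod(str, enum.Enum):
    MMD = "MMD"
    CDI = "CDI"
    RANDOM = "RANDOM"


class SolutionStatus(str, enum.Enum):
    OPTIMAL = "OPTIMAL"
    INFEASIBLE = "INFEASIBLE"
    TIME_LIMIT = "TIME_LIMIT"


@dataclass(frozen=True)
class AssemblyProblem:
    """Coefficients and constraints of one MMD assembly instance."""

    V: np.ndarray = field(repr=False)
    J: int
    f1: np.ndarray = field(repr=False)
    f2: float
    b: np.ndarray = field(repr=False)
    constraint_mode: ConstraintMode
    q: QMatrix | None = None
    ic_counts: dict[int, int] | None = None
    ac_min: int | None = None

    @property
    def n_items(self) -> int:
        return self.V.shape[1]


@dataclass(frozen=True)
class AssemblySolution:
    """Result of one assembly: binary selection, slack, objective, status."""

    x: np.ndarray = field(repr=False)
    y: float
    objective: float
    status: SolutionStatus
    method: AssemblyMethod

    @property
    def items(self) -> np.ndarray:
        """Indices of the selected items."""
        return np.flatnonzero(self.x)


def _validate_constraints(
    mode: ConstraintMode,
    J: int,
    q: QMatrix | None,
    ic_counts: dict[int, int] | None,
    ac_min: int | None,
):
    if mode is ConstraintMode.IC:
        if q is None:
            raise ValueError("IC mode requires the Q-matrix")
        if ic_counts is None:
            if q.n_attributes == 4:
                ic_counts = dict(DEFAULT_IC_COUNTS_K4)
            else:
                raise ValueError(
                    "IC mode requires explicit ic_counts when K != 4 "
                    "(the default blueprint {1:4, 2:7, 3:9} is K=4-specific)"
                )
        total = sum(ic_counts.values())
        if total != J:
            raise ValueError(f"ic_counts sum to {total}, must equal test length J={J}")
    if mode is ConstraintMode.AC:
        if q is None:
            raise ValueError("AC mode requires the Q-matrix")
        if ac_min is None:
            ac_min = DEFAULT_AC_MIN
        max_per_item = int(q.attributes_per_item().max())
        if ac_min * q.n_attributes > J * max_per_item:
            raise ValueError(
                f"AC coverage ac_min={ac_min} over {q.n_attributes} attributes "
                f"cannot be met by {J} items measuring at most {max_per_item} each"
            )
    return ic_counts, ac_min


def build_problem(
    V: StackedDistanceMatrix | np.ndarray,
    J: int,
    constraint_mode: ConstraintMode | str = ConstraintMode.NC,
    q: QMatrix | None = None,
    ic_counts: dict[int, int] | None = None,
    ac_min: int | None = None,
) -> AssemblyProblem:
    """Assemble the MMD objective/constraint coefficients from ``V``.

    All coefficients are means over the rows actually present in ``V``:
    ``f1_j = -mean(V[:, j])``, ``f2 = J * mean(V)``, ``b_t = J * mean(V[t, :])``.
    With the FULL pair set this matches the T(T-1)-denominator definitions;
    with the SIMPLIFIED set the same means are taken over its T*K rows,
    which keeps the program identically scaled.
    """
    mode = ConstraintMode.coerce(constraint_mode)
    Varr = V.V if isinstance(V, StackedDistanceMatrix) else np.asarray(V, dtype=float)
    if Varr.ndim != 2:
        raise ValueError("V must be a 2-D pair-by-item matrix")
    M = Varr.shape[1]
    if not 1 <= J <= M:
        raise ValueError(f"test length J={J} must lie in [1, M={M}]")
    ic_counts, ac_min = _validate_constraints(mode, J, q, ic_counts, ac_min)
    f1 = -Varr.mean(axis=0)
    f2 = float(J * Varr.mean())
    b = J * Varr.mean(axis=1)
    return AssemblyProblem(
        V=Varr, J=J, f1=f1, f2=f2, b=b,
        constraint_mode=mode, q=q, ic_counts=ic_counts, ac_min=ac_min,
    )


def _blueprint_constraints(problem: AssemblyProblem) -> list[LinearConstraint]:
    """IC/AC constraint rows over the x-part of the decision vector."""
    M = problem.n_items
    cons: list[LinearConstraint] = []
    if problem.constraint_mode is ConstraintMode.IC:
        counts = problem.q.attributes_per_item()
        for a, quota in sorted(problem.ic_counts.items()):
            row = np.zeros(M + 1)
            row[:M] = counts == a
            cons.append(LinearConstraint(row, quota, quota))
    elif problem.constraint_mode is ConstraintMode.AC:
        for k in range(problem.q.n_attributes):
            row = np.zeros(M + 1)
            row[:M] = problem.q.entries[:, k]
            cons.append(LinearConstraint(row, problem.ac_min, np.inf))
    return cons


def solve_mmd(problem: AssemblyProblem, time_limit: float | None = None) -> AssemblySolution:
    """Solve the MMD mixed-integer linear program to proven optimality.

    Decision vector is ``(x_1..x_M, y)`` with ``x`` binary and ``y`` free.
    Uses the HiGHS branch-and-bound backend with zero relative optimality
    gap. With a ``time_limit`` (seconds) the incumbent is returned with
    ``TIME_LIMIT`` status if optimality was not proven in time.
    """
    M = problem.n_items
    c = np.concatenate([problem.f1, [problem.f2]])
    integrality = np.concatenate([np.ones(M), [0]])
    bounds = Bounds(
        lb=np.concatenate([np.zeros(M), [-np.inf]]),
        ub=np.concatenate([np.ones(M), [np.inf]]),
    )
    A_slack = np.hstack([problem.V, np.ones((problem.V.shape[0], 1))])
    constraints = [
        LinearConstraint(A_slack, problem.b, np.inf),
        LinearConstraint(np.concatenate([np.ones(M), [0]]), problem.J, problem.J),
    ]
    constraints.extend(_blueprint_constraints(problem))
    options: dict = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=c, constraints=constraints, integrality=integrality, bounds=bounds,
        options=options,
    )
    if res.status == 0:
        status = SolutionStatus.OPTIMAL
    elif res.status == 1 and res.x is not None:
        status = SolutionStatus.TIME_LIMIT
    else:
        return AssemblySolution(
            x=np.zeros(M, dtype=np.int8), y=float("nan"),
            objective=float("nan"), status=SolutionStatus.INFEASIBLE,
            method=AssemblyMethod.MMD,
        )
    x = np.round(res.x[:M]).astype(np.int8)
    # recompute slack at the returned selection: y* = max_t (b_t - V_t.x)
    y = float(np.max(problem.b - problem.V @ x))
    objective = float(problem.f1 @ x + problem.f2 * y)
    return AssemblySolution(x=x, y=y, objective=objective, status=status,
                            method=AssemblyMethod.MMD)


def cdi_index(item_column: np.ndarray, space: LatentClassSpace) -> float:
    """Cognitive diagnostic index of one item.

    The inverse-Hamming-weighted mean of the item's pairwise KL distances
    over all ordered class pairs:

        CDI_j = sum_{u != v} h(u,v)^-1 D(u,v,j) / sum_{u != v} h(u,v)^-1

    where ``h`` is the Hamming distance between attribute patterns. Nearby
    classes (hard to separate) get the largest weight.
    """
    return float(cdi_indices(np.asarray(item_column, dtype=float)[:, None], space)[0])


def cdi_indices(probs: np.ndarray, space: LatentClassSpace) -> np.ndarray:
    """Vectorized CDI for every item column of a class-by-item table."""
    probs = np.asarray(probs, dtype=float)
    index = full_pairs(space)
    u, v = index.pairs[:, 0], index.pairs[:, 1]
    h = (space.patterns[u] != space.patterns[v]).sum(axis=1).astype(float)
    w = 1.0 / h
    D = kl_distance(probs[u, :], probs[v, :])  # (R, M)
    return (w @ D) / w.sum()


def _stratum_masks(q: QMatrix, ic_counts: dict[int, int]):
    counts = q.attributes_per_item()
    return {a: counts == a for a in ic_counts}


def assemble_cdi(
    q: QMatrix,
    cdi: np.ndarray,
    J: int,
    constraint_mode: ConstraintMode | str = ConstraintMode.NC,
    ic_counts: dict[int, int] | None = None,
    ac_min: int | None = None,
) -> AssemblySolution:
    """Greedy CDI assembly: pick the highest-CDI items subject to the blueprint.

    NC: the J largest-CDI items (ties to the smallest item index). IC: the
    top items within each attribute-count stratum at its quota. AC: greedy
    by CDI with a feasibility guard — when an attribute's remaining coverage
    deficit equals the remaining open slots, only items covering a deficient
    attribute may be chosen.
    """
    mode = ConstraintMode.coerce(constraint_mode)
    cdi = np.asarray(cdi, dtype=float)
    M = q.n_items
    if not 1 <= J <= M:
        raise ValueError(f"test length J={J} must lie in [1, M={M}]")
    ic_counts, ac_min = _validate_constraints(mode, J, q, ic_counts, ac_min)
    # stable sort on -cdi: ties resolve to the smallest item index
    order = np.argsort(-cdi, kind="stable")
    x = np.zeros(M, dtype=np.int8)
    if mode is ConstraintMode.NC:
        x[order[:J]] = 1
    elif mode is ConstraintMode.IC:
        masks = _stratum_masks(q, ic_counts)
        for a, quota in ic_counts.items():
            stratum = order[masks[a][order]]
            if len(stratum) < quota:
                raise ValueError(
                    f"stratum of {a}-attribute items has {len(stratum)} items, "
                    f"fewer than its quota {quota}"
                )
            x[stratum[:quota]] = 1
    else:  # AC
        deficit = np.full(q.n_attributes, ac_min, dtype=int)
        chosen: list[int] = []
        remaining = list(order)
        while len(chosen) < J:
            slots_left = J - len(chosen)
            must_cover = deficit > 0
            # feasibility guard: every remaining pick must reduce the deficit
            # once deficits could exhaust the remaining slots
            if must_cover.any() and deficit[must_cover].max() >= slots_left:
                pool = [j for j in remaining if (q.entries[j][must_cover] == 1).any()]
            else:
                pool = remaining
            if not pool:
                raise ValueError("AC coverage repair failed: no eligible item left")
            pick = pool[0]
            chosen.append(pick)
            remaining.remove(pick)
            deficit -= q.entries[pick]
        if (deficit > 0).any():
            raise ValueError("AC coverage not met by greedy selection")
        x[chosen] = 1
    return AssemblySolution(x=x, y=float("nan"), objective=float(cdi @ x),
                            status=SolutionStatus.OPTIMAL, method=AssemblyMethod.CDI)


def assemble_random(
    q: QMatrix,
    J: int,
    constraint_mode: ConstraintMode | str = ConstraintMode.NC,
    ic_counts: dict[int, int] | None = None,
    ac_min: int | None = None,
    rng: np.random.Generator | None = None,
    max_rejections: int = 10_000,
) -> AssemblySolution:
    """Random assembly under the same blueprint modes, reproducible by seed.

    NC: uniform J-subset. IC: uniform subset within each attribute-count
    stratum at its quota. AC: rejection sampling of uniform J-subsets until
    coverage holds (capped), then greedy coverage repair by swapping in
    items that cover deficient attributes.
    """
    mode = ConstraintMode.coerce(constraint_mode)
    rng = np.random.default_rng() if rng is None else rng
    M = q.n_items
    if not 1 <= J <= M:
        raise ValueError(f"test length J={J} must lie in [1, M={M}]")
    ic_counts, ac_min = _validate_constraints(mode, J, q, ic_counts, ac_min)
    x = np.zeros(M, dtype=np.int8)
    if mode is ConstraintMode.NC:
        x[rng.choice(M, size=J, replace=False)] = 1
    elif mode is ConstraintMode.IC:
        masks = _stratum_masks(q, ic_counts)
        for a, quota in ic_counts.items():
            stratum = np.flatnonzero(masks[a])
            if len(stratum) < quota:
                raise ValueError(
                    f"stratum of {a}-attribute items has {len(stratum)} items, "
                    f"fewer than its quota {quota}"
                )
            x[rng.choice(stratum, size=quota, replace=False)] = 1
    else:  # AC
        ok = False
        for _ in range(max_rejections):
            cand = rng.choice(M, size=J, replace=False)
            if (q.entries[cand].sum(axis=0) >= ac_min).all():
                x[cand] = 1
                ok = True
                break
        if not ok:
            # greedy repair: swap in items covering the most deficient
            # attribute, dropping the item with the largest coverage surplus
            cand = list(rng.choice(M, size=J, replace=False))
            for _ in range(2 * M):
                coverage = q.entries[cand].sum(axis=0)
                deficient = np.flatnonzero(coverage < ac_min)
                if deficient.size == 0:
                    break
                k = int(deficient[np.argmin(coverage[deficient])])
                pool = [j for j in range(M) if j not in cand and q.entries[j, k] == 1]
                if not pool:
                    raise ValueError("AC coverage repair failed: bank cannot cover")
                # surplus contribution of each candidate if removed
                surplus = [int((q.entries[j] * (coverage - ac_min))[q.entries[j] == 1].min(initial=M))
                           for j in cand]
                drop = cand[int(np.argmax(surplus))]
                cand.remove(drop)
                cand.append(int(rng.choice(pool)))
            coverage = q.entries[cand].sum(axis=0)
            if (coverage < ac_min).any():
                raise ValueError("AC coverage repair failed after swaps")
            x[cand] = 1
    return AssemblySolution(x=x, y=float("nan"), objective=float("nan"),
                            status=SolutionStatus.OPTIMAL, method=AssemblyMethod.RANDOM)
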