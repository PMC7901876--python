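"""Monte-Carlo harness: bank generation, examinees, responses, MAP scoring.

A replication of the evaluation experiment proceeds as:

1. Generate an item bank: Q-matrix rows are binary expansions of uniform
   integers in ``[1, 2**K - 1]``; DINA/DINO slip and guess parameters are
   drawn from U(0.05, 0.4), R-RUM baselines from U(0.75, 0.95) and
   penalties from U(0.2, 0.95).
2. Generate two examinee groups by thresholding correlated multivariate
   normal latent traits at zero (mastery iff the latent value is >= 0;
   the off-diagonal correlation is ``rho``). One group supplies the
   empirical prior over latent classes, the other is classified.
3. Assemble a test from the bank with each configured method (maximin MILP,
   CDI-greedy, random) under the configured constraint mode; all methods
   within a replication share the same bank and examinees.
4. Simulate item responses on each assembled test (uniform draw per cell
   against the model's correct-response probability).
5. Classify the test group by maximum a-posteriori over latent classes
   using the empirical prior, and score attribute-wise (ACR) and
   whole-pattern (PCR) agreement with the generating truth.

Per-replication child seeds are spawned deterministically from the master
seed so any replication can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import (
    AssemblyMethod,
    AssemblySolution,
    ConstraintMode,
    assemble_cdi,
    assemble_random,
    build_problem,
    cdi_indices,
    solve_mmd,
)
from .cdm_core import (
    ItemParameters,
    LatentClassSpace,
    Model,
    ProbabilityTable,
    QMatrix,
    class_probability_table,
    enumerate_latent_classes,
)
from .class_distance import PairMode, stack_distances

__all__ = [
    "Population",
    "PopulationRole",
    "ResponseMatrix",
    "EvaluationResult",
    "AnovaResult",
    "ExperimentConfig",
    "generate_item_bank",
    "generate_examinees",
    "simulate_responses",
    "empirical_prior",
    "map_classify",
    "evaluate",
    "expected_pcr_independent",
    "one_way_anova",
    "run_experiment",
    "summarize",
    "outperform_proportions",
    "desk_study_configs",
]


class PopulationRole(str, Enum):
    PRIOR_GROUP = "PRIOR_GROUP"
    TEST_GROUP = "TEST_GROUP"


@dataclass(frozen=True)
class Population:
    """Examinee attribute patterns generated under a correlation structure."""

    alphas: np.ndarray = field(repr=False)  # (N, K) binary
    rho: float
    role: PopulationRole

    @property
    def N(self) -> int:
        return self.alphas.shape[0]

    @property
    def K(self) -> int:
        return self.alphas.shape[1]


@dataclass(frozen=True)
class ResponseMatrix:
    """Binary item responses of a population on an assembled test."""

    X: np.ndarray = field(repr=False)  # (N, J) binary
    item_ids: np.ndarray  # bank indices of the test items


@dataclass(frozen=True)
class EvaluationResult:
    """Attribute (ACR) and pattern (PCR) correct classification rates."""

    ACR: float
    PCR: float
    N: int
    K: int


@dataclass(frozen=True)
class AnovaResult:
    """Balanced one-way ANOVA with two groups on (1, 2n-2) df."""

    S_A: float
    S_E: float
    F: float
    p: float
    n: int
    group_means: tuple[float, float]
    significant: bool


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of one Monte-Carlo experiment.

    Defaults are desk-scale (50 replications of N=2000 examinees per group);
    the published full-scale design used 200 replications of N=10000.
    """

    model: Model | str = Model.DINA
    K: int = 4
    M: int = 300
    N: int = 2000
    J: int = 20
    rho: float = 0.0
    constraint_mode: ConstraintMode | str = ConstraintMode.NC
    methods: tuple[str, ...] = ("mmd", "cdi", "random")
    distance_mode: PairMode | str = PairMode.SIMPLIFIED
    replications: int = 50
    seed: int = 0
    ic_counts: dict[int, int] | None = None
    ac_min: int | None = None
    prior_floor: float = 0.0
    #: Seconds allowed per maximin MILP solve; the incumbent is used if
    #: optimality is not proven in time (it typically stabilizes within a
    #: couple of seconds while the dual bound lags far behind). None =
    #: solve to proven optimality.
    milp_time_limit: float | None = 3.0

    def __post_init__(self):
        object.__setattr__(self, "model", Model.coerce(self.model))
        object.__setattr__(self, "constraint_mode", ConstraintMode.coerce(self.constraint_mode))
        object.__setattr__(self, "distance_mode", PairMode.coerce(self.distance_mode))


def generate_item_bank(
    M: int, K: int, model: Model | str, rng: np.random.Generator
) -> tuple[QMatrix, ItemParameters]:
    """Draw a random calibrated item bank.

    Q rows are the binary expansions of M uniform integers on
    ``[1, 2**K - 1]`` (so no item measures zero attributes and every
    attribute profile is equally likely). DINA/DINO: ``s_j, g_j`` iid
    U(0.05, 0.4). R-RUM: ``pi*_j`` iid U(0.75, 0.95), ``r*_jk`` iid
    U(0.2, 0.95) on measured attributes (NaN elsewhere).
    """
    model = Model.coerce(model)
    codes = rng.integers(1, 2**K, size=M)  # [1, 2^K - 1] inclusive
    shifts = np.arange(K - 1, -1, -1)
    entries = ((codes[:, None] >> shifts[None, :]) & 1).astype(np.int8)
    q = QMatrix(entries)
    if model in (Model.DINA, Model.DINO):
        slip = rng.uniform(0.05, 0.4, size=M)
        guess = rng.uniform(0.05, 0.4, size=M)
        params = ItemParameters(model=model, slip=slip, guess=guess)
    else:
        baseline = rng.uniform(0.75, 0.95, size=M)
        penalty = rng.uniform(0.2, 0.95, size=(M, K))
        penalty = np.where(entries == 1, penalty, np.nan)
        params = ItemParameters(model=model, baseline=baseline, penalty=penalty)
    return q, params


def generate_examinees(
    N: int, K: int, rho: float, rng: np.random.Generator,
    role: PopulationRole = PopulationRole.TEST_GROUP,
) -> Population:
    """Correlated binary attribute patterns via a thresholded Gaussian copula.

    Latent traits are multivariate normal with zero mean, unit variances and
    common correlation ``rho``; attribute k is mastered iff its latent value
    is >= 0 (ties map to mastery). With ``rho = 0`` every pattern is equally
    likely; larger ``rho`` concentrates mass on the all-zero and all-one
    patterns.
    """
    if not 0 <= rho < 1:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    sigma = np.full((K, K), rho)
    np.fill_diagonal(sigma, 1.0)
    # equicorrelation with rho in [0, 1) is positive definite for all K
    latent = rng.multivariate_normal(np.zeros(K), sigma, size=N, method="cholesky")
    alphas = (latent >= 0).astype(np.int8)
    return Population(alphas=alphas, rho=rho, role=role)


def simulate_responses(
    items: np.ndarray,
    table: ProbabilityTable,
    pop: Population,
    space: LatentClassSpace,
    rng: np.random.Generator,
) -> ResponseMatrix:
    """Bernoulli response simulation on a test: ``X_ij = 1`` iff ``u <= P``.

    ``table`` must cover the full bank; ``items`` are bank indices of the
    assembled test.
    """
    items = np.asarray(items)
    classes = space.pattern_index(pop.alphas)  # (N,)
    P = table.probs[np.ix_(classes, items)]  # (N, J)
    u = rng.uniform(size=P.shape)
    X = (u <= P).astype(np.int8)
    return ResponseMatrix(X=X, item_ids=items)


def empirical_prior(pop: Population, space: LatentClassSpace) -> np.ndarray:
    """Relative frequency of each latent class in a (prior) population."""
    classes = space.pattern_index(pop.alphas)
    counts = np.bincount(classes, minlength=space.T).astype(float)
    return counts / counts.sum()


def map_classify(
    responses: ResponseMatrix,
    table: ProbabilityTable,
    prior: np.ndarray,
    space: LatentClassSpace,
) -> np.ndarray:
    """Maximum a-posteriori latent-class assignment per examinee.

    Maximizes ``log prior(c) + sum_j [X_ij log P_j(c) + (1-X_ij) log(1-P_j(c))]``
    over classes with nonzero prior; ties break to the smallest class index.
    Returns the (N, K) matrix of estimated attribute patterns.
    """
    prior = np.asarray(prior, dtype=float)
    if prior.sum() <= 0:
        raise ValueError("prior has no support (all zero)")
    support = np.flatnonzero(prior > 0)
    P = table.probs[np.ix_(support, responses.item_ids)]  # (S, J)
    logp = np.log(P)
    log1m = np.log1p(-P)
    X = responses.X.astype(float)
    # (N, S) log-posterior up to a constant
    ll = X @ logp.T + (1.0 - X) @ log1m.T + np.log(prior[support])
    best = support[np.argmax(ll, axis=1)]  # argmax takes first max: smallest index
    return space.patterns[best]


def evaluate(alphas_hat: np.ndarray, alphas_true: np.ndarray) -> EvaluationResult:
    """Attribute- and pattern-level agreement between estimate and truth."""
    alphas_hat = np.asarray(alphas_hat)
    alphas_true = np.asarray(alphas_true)
    if alphas_hat.shape != alphas_true.shape:
        raise ValueError(
            f"shape mismatch: {alphas_hat.shape} vs {alphas_true.shape}"
        )
    agree = alphas_hat == alphas_true
    N, K = alphas_true.shape
    return EvaluationResult(
        ACR=float(agree.mean()),
        PCR=float(agree.all(axis=1).mean()),
        N=N, K=K,
    )


def expected_pcr_independent(acr_per_attribute) -> float:
    """Whole-pattern rate implied by independent per-attribute rates.

    If attribute classifications were independent the pattern rate would be
    the product of the per-attribute rates — e.g. rates (0.1, 0.9) average
    to 0.5 yet imply a pattern rate of only 0.09, while the lower-average
    (0.4, 0.4) implies 0.16.
    """
    rates = np.asarray(acr_per_attribute, dtype=float)
    if ((rates < 0) | (rates > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    return float(np.prod(rates))


def one_way_anova(y1, y2, alpha: float = 0.05) -> AnovaResult:
    """Balanced two-group one-way ANOVA.

    ``S_A`` is the between-group sum of squares, ``S_E`` the within-group
    sum of squares; ``F = S_A / (S_E / (2n - 2))`` on (1, 2n-2) degrees of
    freedom with the exact F-distribution upper tail as p-value.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("y1 and y2 must be 1-D vectors of equal length")
    n = len(y1)
    if n < 2:
        raise ValueError("need at least two observations per group")
    m1, m2 = y1.mean(), y2.mean()
    grand = (m1 + m2) / 2.0
    S_A = n * ((m1 - grand) ** 2 + (m2 - grand) ** 2)
    S_E = ((y1 - m1) ** 2).sum() + ((y2 - m2) ** 2).sum()
    df_e = 2 * n - 2
    if S_E == 0:
        F = 0.0 if S_A == 0 else float("inf")
    else:
        F = float(S_A / (S_E / df_e))
    p = float(stats.f.sf(F, 1, df_e))
    return AnovaResult(S_A=float(S_A), S_E=float(S_E), F=F, p=p, n=n,
                       group_means=(float(m1), float(m2)),
                       significant=bool(p < alpha))


def _assemble(
    method: str,
    config: ExperimentConfig,
    q: QMatrix,
    table: ProbabilityTable,
    space: LatentClassSpace,
    rng: np.random.Generator,
) -> AssemblySolution:
    method = method.lower()
    common = dict(constraint_mode=config.constraint_mode,
                  ic_counts=config.ic_counts, ac_min=config.ac_min)
    if method in ("mmd", "mmd_full"):
        mode = PairMode.FULL if method == "mmd_full" else config.distance_mode
        V = stack_distances(table, mode=mode, space=space, allow_large_full=True)
        problem = build_problem(V, config.J, q=q, **common)
        return solve_mmd(problem, time_limit=config.milp_time_limit)
    if method == "cdi":
        cdi = cdi_indices(table.probs, space)
        return assemble_cdi(q, cdi, config.J, **common)
    if method == "random":
        return assemble_random(q, config.J, rng=rng, **common)
    raise ValueError(f"unknown assembly method {method!r}")


def run_replication(
    config: ExperimentConfig, rep: int, seed_seq: np.random.SeedSequence
) -> list[dict]:
    """One paired replication: shared bank and examinees, all methods."""
    space = enumerate_latent_classes(config.K)
    rng_bank, rng_prior, rng_test, rng_assembly, rng_resp = (
        np.random.default_rng(s) for s in seed_seq.spawn(5)
    )
    q, params = generate_item_bank(config.M, config.K, config.model, rng_bank)
    table = class_probability_table(q, params, space)
    prior_pop = generate_examinees(config.N, config.K, config.rho, rng_prior,
                                   role=PopulationRole.PRIOR_GROUP)
    test_pop = generate_examinees(config.N, config.K, config.rho, rng_test,
                                  role=PopulationRole.TEST_GROUP)
    prior = empirical_prior(prior_pop, space)
    if config.prior_floor > 0:
        prior = prior + config.prior_floor
        prior /= prior.sum()
    rows = []
    for method in config.methods:
        solution = _assemble(method, config, q, table, space, rng_assembly)
        responses = simulate_responses(solution.items, table, test_pop, space, rng_resp)
        alphas_hat = map_classify(responses, table, prior, space)
        result = evaluate(alphas_hat, test_pop.alphas)
        rows.append({
            "rep": rep,
            "method": method,
            "constraint": config.constraint_mode.value,
            "acr": result.ACR,
            "pcr": result.PCR,
        })
    return rows


def run_experiment(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Run all replications; returns the long table (rep, method, constraint, acr, pcr).

    Within each replication every method sees the same bank and the same
    examinee groups, so method comparisons are paired. Child seeds come from
    a spawned :class:`numpy.random.SeedSequence` per replication, making any
    single replication reproducible in isolation.
    """
    master = np.random.SeedSequence(config.seed)
    rep_seeds = master.spawn(config.replications)
    rows: list[dict] = []
    for rep, seq in enumerate(rep_seeds):
        rows.extend(run_replication(config, rep, seq))
        if progress and (rep + 1) % 10 == 0:
            print(f"  replication {rep + 1}/{config.replications}")
    return pd.DataFrame(rows)


def desk_study_configs(seed: int = 0) -> dict[str, ExperimentConfig]:
    """Desk-scale versions of the published method-comparison conditions.

    Four unconstrained (NC) runs at correlation 0 with a 300-item bank and a
    20-item test: the three models at K=4 with 50 replications of N=2000
    examinees per group, and DINA at K=8 with 30 replications (simplified
    distances throughout; the K=8 maximin solve gets a larger per-solve
    budget because its program has 2048 rows instead of 64). The published
    full-scale design used 200 replications of N=10000.
    """
    base = dict(M=300, N=2000, J=20, rho=0.0, constraint_mode="NC",
                distance_mode="SIMPLIFIED", replications=50)
    return {
        "dina_k4": ExperimentConfig(model="DINA", K=4, seed=seed,
                                    methods=("mmd", "cdi", "random"), **base),
        "dino_k4": ExperimentConfig(model="DINO", K=4, seed=seed + 1,
                                    methods=("mmd",), **base),
        "rrum_k4": ExperimentConfig(model="RRUM", K=4, seed=seed + 2,
                                    methods=("mmd",), **base),
        "dina_k8": ExperimentConfig(model="DINA", K=8, seed=seed + 3,
                                    methods=("mmd",), milp_time_limit=10.0,
                                    **{**base, "replications": 30}),
    }


def summarize(long_table: pd.DataFrame) -> pd.DataFrame:
    """Mean ACR/PCR per method and constraint mode."""
    return (
        long_table.groupby(["method", "constraint"], sort=False)[["acr", "pcr"]]
        .mean()
        .reset_index()
    )


def outperform_proportions(long_table: pd.DataFrame, metric: str = "pcr") -> pd.DataFrame:
    """Pairwise per-replication win proportions between methods.

    For each ordered method pair (a, b), the fraction of replications in
    which a's metric strictly exceeds b's.
    """
    wide = long_table.pivot_table(index=["rep", "constraint"], columns="method",
                                  values=metric)
    methods = list(wide.columns)
    rows = []
    for constraint, block in wide.groupby(level="constraint"):
        for a in methods:
            for b in methods:
                if a == b:
                    continue
                rows.append({
                    "constraint": constraint,
                    "better": a,
                    "worse": b,
                    "metric": metric,
                    "proportion": float((block[a] > block[b]).mean()),
                })
    return pd.DataFrame(rows)
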