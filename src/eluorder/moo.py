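"""Multi-objective re-optimization of QSRR coefficients.

The retention model's coefficient vector is re-optimized against two
objectives evaluated on the training set,

    f1 = %RMSE(t_R)      (retention-time error)
    f2 = %RMSE(order)    (elution-order error)

by an elitist non-dominated-sorting genetic algorithm (NSGA-II-style ranking
and crowding, simulated-binary crossover, polynomial mutation).  The MLR
solution is seeded into the initial population, so elitism guarantees that
the final front weakly dominates the control: there is always a front point
with f1 <= control.f1 and f2 <= control.f2.

From the front, a compromise is picked in two steps: the knee point (closest
to the ideal corner after min-max normalization) orients the user, then
``select_solution`` minimizes the order error subject to a user bound on the
relative increase of the retention error over the control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core_data import AnalyteTable, CaseStudyConfig, GAParams
from .errors import ValidationError
from .qsrr import QSRRModel, design_matrix, elution_ranks

__all__ = [
    "ParetoSolution",
    "ParetoFront",
    "pareto_filter",
    "optimize_moo",
    "knee_point",
    "select_solution",
    "annotate_front",
    "compare_to_control",
]

_EPS_FLOOR = 1e-3  # scale floor for perturbing near-zero coefficients
_ETA_CROSSOVER = 15.0
_ETA_MUTATION = 20.0


@dataclass(frozen=True)
class ParetoSolution:
    """One candidate coefficient vector with its objective pair (percent)."""

    coefficients: np.ndarray  # (K+1,) intercept first
    f1: float
    f2: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if not np.all(np.isfinite(coef)):
            raise ValidationError("solution coefficients must be finite")

    @property
    def objectives(self) -> tuple[float, float]:
        return (self.f1, self.f2)


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated solutions sorted by ascending f1, plus the MLR control."""

    solutions: tuple[ParetoSolution, ...]
    control: ParetoSolution | None = None
    knee_index: int | None = None
    selected_index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "solutions", tuple(self.solutions))
        f1 = [s.f1 for s in self.solutions]
        if f1 != sorted(f1):
            raise ValidationError("front solutions must be sorted by ascending f1")

    def __len__(self) -> int:
        return len(self.solutions)

    def objective_array(self) -> np.ndarray:
        return np.array([[s.f1, s.f2] for s in self.solutions], dtype=float)


def _objectives_of(p) -> tuple[float, float]:
    if isinstance(p, ParetoSolution):
        return p.objectives
    f1, f2 = float(p[0]), float(p[1])
    return f1, f2


def pareto_filter(points: Sequence) -> list:
    """Return the non-dominated subset of ``points``.

    Points may be ``ParetoSolution`` objects or ``(f1, f2, ...)`` tuples.
    A point dominates another if it is no worse in both objectives and
    strictly better in at least one.  Duplicates in objective space collapse
    to the first occurrence.  Input order is preserved among survivors.
    """
    objs = [_objectives_of(p) for p in points]
    keep: list = []
    seen: set[tuple[float, float]] = set()
    for i, (f1, f2) in enumerate(objs):
        if not (np.isfinite(f1) and np.isfinite(f2)):
            continue
        if (f1, f2) in seen:
            continue
        dominated = any(
            (g1 <= f1 and g2 <= f2) and (g1 < f1 or g2 < f2) for g1, g2 in objs
        )
        if not dominated:
            keep.append(points[i])
            seen.add((f1, f2))
    return keep


# --- NSGA-II machinery -----------------------------------------------------


def _nondominated_rank(F: np.ndarray) -> np.ndarray:
    """Fast non-dominated sorting; returns the front rank of each point."""
    P = len(F)
    ranks = np.full(P, -1, dtype=int)
    d0 = F[:, None, 0] <= F[None, :, 0]
    d1 = F[:, None, 1] <= F[None, :, 1]
    s0 = F[:, None, 0] < F[None, :, 0]
    s1 = F[:, None, 1] < F[None, :, 1]
    dominates = d0 & d1 & (s0 | s1)  # dominates[i, j]: i dominates j
    n_dominators = dominates.sum(axis=0)
    front = np.where(n_dominators == 0)[0]
    r = 0
    while len(front):
        ranks[front] = r
        n_dominators = n_dominators - dominates[front].sum(axis=0)
        n_dominators[ranks >= 0] = -1
        front = np.where(n_dominators == 0)[0]
        r += 1
    return ranks


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    m = len(F)
    if m <= 2:
        return np.full(m, np.inf)
    dist = np.zeros(m)
    for j in range(F.shape[1]):
        order = np.argsort(F[:, j], kind="stable")
        span = F[order[-1], j] - F[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            gaps = (F[order[2:], j] - F[order[:-2], j]) / span
            dist[order[1:-1]] += gaps
    return dist


def _evaluate_population(
    coefs: np.ndarray,
    D: np.ndarray,
    t_obs: np.ndarray,
    obs_ranks: np.ndarray,
    variant: str,
) -> np.ndarray:
    """Vectorized (f1, f2) for a whole population of coefficient vectors.

    Uses the same stable-sort rank convention as :func:`~eluorder.qsrr.elution_ranks`;
    non-finite predictions yield infinite objectives (worst rank).
    """
    pred = coefs @ D.T  # (P, n)
    n = D.shape[0]
    rel = (pred - t_obs) / t_obs
    with np.errstate(invalid="ignore", over="ignore"):
        if variant == "signed_mean":
            f1 = 100.0 * rel.mean(axis=1)
        else:
            f1 = 100.0 * np.sqrt(np.mean(rel**2, axis=1))
    order = np.argsort(pred, axis=1, kind="stable")
    ranks = np.argsort(order, axis=1) + 1  # inverse permutation = ranks
    rel_r = (ranks - obs_ranks) / obs_ranks.astype(float)
    if variant == "signed_mean":
        f2 = 100.0 * rel_r.mean(axis=1)
    else:
        f2 = 100.0 * np.sqrt(np.mean(rel_r**2, axis=1))
    F = np.column_stack([f1, f2])
    F[~np.isfinite(pred).all(axis=1)] = np.inf
    F[~np.isfinite(F).all(axis=1)] = np.inf
    return F


def _tournament(
    rng: np.random.Generator, ranks: np.ndarray, crowd: np.ndarray, n_pick: int
) -> np.ndarray:
    a = rng.integers(0, len(ranks), size=n_pick)
    b = rng.integers(0, len(ranks), size=n_pick)
    better_b = (ranks[b] < ranks[a]) | ((ranks[b] == ranks[a]) & (crowd[b] > crowd[a]))
    return np.where(better_b, b, a)


def _sbx_crossover(
    rng: np.random.Generator, p1: np.ndarray, p2: np.ndarray, prob: float
) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = p1.copy(), p2.copy()
    n_pairs, n_var = p1.shape
    do_pair = rng.random(n_pairs) < prob
    do_gene = (rng.random((n_pairs, n_var)) < 0.5) & do_pair[:, None]
    u = rng.random((n_pairs, n_var))
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (_ETA_CROSSOVER + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (_ETA_CROSSOVER + 1.0)),
    )
    child1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    child2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    c1[do_gene] = child1[do_gene]
    c2[do_gene] = child2[do_gene]
    return c1, c2


def _polynomial_mutation(
    rng: np.random.Generator, pop: np.ndarray, scale: np.ndarray, prob: float
) -> np.ndarray:
    out = pop.copy()
    mask = rng.random(pop.shape) < prob
    u = rng.random(pop.shape)
    delta = np.where(
        u < 0.5,
        (2.0 * u) ** (1.0 / (_ETA_MUTATION + 1.0)) - 1.0,
        1.0 - (2.0 * (1.0 - u)) ** (1.0 / (_ETA_MUTATION + 1.0)),
    )
    out[mask] = (pop + delta * scale)[mask]
    return out


def optimize_moo(
    table: AnalyteTable,
    train: Sequence[int],
    init: QSRRModel,
    params: GAParams | None = None,
    config: CaseStudyConfig | None = None,
) -> ParetoFront:
    """Re-optimize the coefficient vector against (f1, f2) on the training set.

    The initial population is the MLR coefficient vector plus
    ``population_size - 1`` Gaussian perturbations with per-gene standard
    deviation ``init_spread * max(|a_k|, 1e-3)``.  The run is elitist and
    fully reproducible for a fixed seed.  Returns the final non-dominated
    set sorted by ascending f1, with ``control`` set to the MLR objective
    pair.
    """
    params = params or GAParams()
    variant = config.rmse_variant if config is not None else "relative_rmse"
    seed = params.seed
    if seed is None:
        seed = config.seed if config is not None else 0
    rng = np.random.default_rng(seed)

    idx = np.asarray(train, dtype=int)
    D = design_matrix(table, idx)
    t_obs = table.t_obs[idx]
    obs_ranks = elution_ranks(t_obs)

    beta0 = init.beta
    n_var = len(beta0)
    scale = params.init_spread * np.maximum(np.abs(beta0), _EPS_FLOOR)
    pop = np.vstack(
        [beta0, beta0 + rng.normal(0.0, 1.0, (params.population_size - 1, n_var)) * scale]
    )
    F = _evaluate_population(pop, D, t_obs, obs_ranks, variant)
    if not np.isfinite(F).all(axis=1).any():
        raise ValidationError("all initial individuals have non-finite objectives")

    half = params.population_size // 2
    for _ in range(params.generations):
        ranks = _nondominated_rank(F)
        crowd = _crowding_full(F, ranks)
        parents1 = _tournament(rng, ranks, crowd, half)
        parents2 = _tournament(rng, ranks, crowd, half)
        c1, c2 = _sbx_crossover(rng, pop[parents1], pop[parents2], params.crossover_prob)
        offspring = np.vstack([c1, c2])
        offspring = _polynomial_mutation(rng, offspring, scale, params.mutation_prob)
        F_off = _evaluate_population(offspring, D, t_obs, obs_ranks, variant)
        pop, F = _environmental_selection(
            np.vstack([pop, offspring]),
            np.vstack([F, F_off]),
            params.population_size,
        )

    f_ctrl = _evaluate_population(beta0[None, :], D, t_obs, obs_ranks, variant)[0]
    control = ParetoSolution(coefficients=beta0, f1=float(f_ctrl[0]), f2=float(f_ctrl[1]))

    finite = np.isfinite(F).all(axis=1)
    candidates = [
        ParetoSolution(coefficients=pop[i], f1=float(F[i, 0]), f2=float(F[i, 1]))
        for i in np.where(finite)[0]
    ]
    front = pareto_filter(candidates)
    front.sort(key=lambda s: (s.f1, s.f2))
    return ParetoFront(solutions=tuple(front), control=control)


def _crowding_full(F: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    crowd = np.zeros(len(F))
    for r in np.unique(ranks):
        members = np.where(ranks == r)[0]
        crowd[members] = _crowding_distance(F[members])
    return crowd


def _environmental_selection(
    pop: np.ndarray, F: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    ranks = _nondominated_rank(F)
    crowd = _crowding_full(F, ranks)
    # Sort by (rank asc, crowding desc); stable so index order breaks ties.
    order = np.lexsort((-crowd, ranks))
    keep = order[:size]
    return pop[keep], F[keep]


def knee_point(front: ParetoFront) -> int:
    """Index of the knee: closest to the ideal corner after normalization.

    Both objectives are min-max normalized over the front to [0, 1]; the knee
    minimizes the Euclidean distance to the normalized ideal point (0, 0).
    Ties break toward lower f1; a single-point front returns 0.
    """
    if len(front) == 0:
        raise ValidationError("cannot locate the knee of an empty front")
    F = front.objective_array()
    lo, hi = F.min(axis=0), F.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (F - lo) / span
    dist = np.hypot(Z[:, 0], Z[:, 1])
    return int(np.argmin(dist))  # solutions sorted by f1: first minimum = lower f1


def select_solution(front: ParetoFront, max_tr_loss_percent: float) -> int:
    """Pick the compromise solution under the user bound on retention loss.

    Feasible solutions satisfy 100*(f1 - control.f1)/control.f1 <=
    ``max_tr_loss_percent``; among them the one with minimum f2 is returned
    (ties toward lower f1).  If no solution is feasible, the one with minimum
    f1 is returned as a conservative fallback.
    """
    if len(front) == 0:
        raise ValidationError("cannot select from an empty front")
    if front.control is None:
        raise ValidationError("front has no control solution")
    c1 = front.control.f1
    F = front.objective_array()
    loss = 100.0 * (F[:, 0] - c1) / c1
    feasible = np.where(loss <= max_tr_loss_percent)[0]
    if len(feasible) == 0:
        return int(np.argmin(F[:, 0]))
    best = feasible[np.lexsort((F[feasible, 0], F[feasible, 1]))[0]]
    return int(best)


def annotate_front(front: ParetoFront, max_tr_loss_percent: float) -> ParetoFront:
    """Return a copy with knee and selected indices filled in."""
    return replace(
        front,
        knee_index=knee_point(front),
        selected_index=select_solution(front, max_tr_loss_percent),
    )


def compare_to_control(
    control: tuple[float, float], selected: tuple[float, float]
) -> tuple[float, float]:
    """Component-wise relative change (%) of the selected point vs the control."""
    c1, c2 = control
    if c1 <= 0 or c2 <= 0:
        raise ValidationError("control objectives must be strictly positive")
    s1, s2 = selected
    return (100.0 * (s1 - c1) / c1, 100.0 * (s2 - c2) / c2)
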