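"""Linear QSRR fitting, Kennard-Stone splitting and the two error metrics.

The retention model is the ordinary linear QSRR

    t_R = a0 + a1*x1 + ... + aK*xK + eps

fitted by multiple linear regression (OLS) on raw descriptors.  The two
metrics that drive the multi-objective stage are the percentage relative
root-mean-square errors of retention time and of elution order:

    %RMSE = 100 * sqrt( (1/n) * sum_i ((pred_i - obs_i) / obs_i)^2 )

applied respectively to retention times in minutes and to 1-based elution
ranks.  The rank metric divides by the observed rank, so a swap among the
earliest-eluting analytes costs far more than the same swap at the end of
the chromatogram — the metric's intended emphasis.  The literal printed form
of the formula (a signed relative mean with neither squaring nor root) is
available as the ``signed_mean`` variant for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core_data import AnalyteTable, CaseStudyConfig
from .errors import SchemaError, SingularDesignError, ValidationError

__all__ = [
    "QSRRModel",
    "SplitResult",
    "kennard_stone_split",
    "fit_mlr",
    "predict",
    "design_matrix",
    "percent_rmse_tr",
    "elution_ranks",
    "percent_rmse_order",
    "evaluate_model",
]


@dataclass(frozen=True)
class QSRRModel:
    """Fitted linear QSRR model: intercept plus one coefficient per descriptor.

    ``intercept`` is in minutes; ``coefficients[k]`` is in minutes per unit of
    descriptor ``descriptor_names[k]``.  ``residual_sd`` is the sample
    standard deviation of the training residuals in minutes.
    """

    intercept: float
    coefficients: np.ndarray
    descriptor_names: tuple[str, ...]
    n_train: int
    residual_sd: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))
        if coef.ndim != 1 or len(coef) != len(self.descriptor_names):
            raise ValidationError("one coefficient per descriptor is required")
        if not (np.isfinite(self.intercept) and np.all(np.isfinite(coef))):
            raise ValidationError("model coefficients must be finite")

    @property
    def beta(self) -> np.ndarray:
        """Full coefficient vector (intercept first)."""
        return np.concatenate(([self.intercept], self.coefficients))


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive train/test row-index sets."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    ratio_achieved: float


def design_matrix(table: AnalyteTable, indices: Sequence[int] | None = None) -> np.ndarray:
    """Design matrix [1 | X] for the given rows (all rows if None)."""
    X = table.X if indices is None else table.X[np.asarray(indices, dtype=int)]
    return np.column_stack([np.ones(len(X)), X])


def _autoscale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant column: no scale information
    return (X - mu) / sd


def kennard_stone_split(table: AnalyteTable, ratio: float) -> SplitResult:
    """Deterministic Kennard-Stone train/test split.

    Selection operates in autoscaled descriptor space.  The first two
    training points are the pair at maximum Euclidean distance; each
    subsequent point maximizes its minimum distance to the points already
    selected (max-min criterion).  Ties are broken by the lowest row index,
    making the split fully deterministic.  The remaining rows form the
    external validation (test) set.
    """
    n = table.n
    if not 0.0 < ratio < 1.0:
        raise ValidationError("split ratio must be in (0, 1)")
    if n < 3:
        raise ValidationError("Kennard-Stone split needs at least 3 analytes")
    n_train = int(np.floor(ratio * n + 0.5))
    if n_train < 2 or n_train > n - 1:
        raise ValidationError(
            f"ratio {ratio} on n={n} leaves an invalid train size {n_train}"
        )
    Z = _autoscale(table.X)
    D = cdist(Z, Z)
    # Seed pair: maximum pairwise distance, lexicographically first on ties.
    iu = np.triu_indices(n, k=1)
    best = np.argmax(D[iu])
    selected = [int(iu[0][best]), int(iu[1][best])]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    for _ in range(n_train - 2):
        nxt = int(np.argmax(min_dist))  # argmax returns the lowest index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    train = tuple(selected)
    test = tuple(i for i in range(n) if i not in set(selected))
    return SplitResult(train, test, ratio_achieved=n_train / n)


def fit_mlr(table: AnalyteTable, train: Sequence[int]) -> QSRRModel:
    """Ordinary least-squares fit of the linear QSRR on the training rows.

    Descriptors are used raw (unscaled), so coefficients are directly
    comparable with published descriptor models.  Raises
    :class:`SingularDesignError` if the intercept-augmented design is rank
    deficient.
    """
    train = np.asarray(train, dtype=int)
    k = table.k
    if len(train) < k + 1:
        raise ValidationError(
            f"need at least K+1={k + 1} training analytes, got {len(train)}"
        )
    A = design_matrix(table, train)
    y = table.t_obs[train]
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularDesignError("design matrix [1 | X] is rank deficient")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = max(len(train) - (k + 1), 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    return QSRRModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        descriptor_names=table.descriptor_names,
        n_train=len(train),
        residual_sd=residual_sd,
    )


def predict(
    model: QSRRModel,
    table: AnalyteTable,
    indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Predicted retention times (minutes) for the given rows."""
    missing = [d for d in model.descriptor_names if d not in table.descriptor_names]
    if missing:
        raise SchemaError(f"table lacks descriptor column(s) {missing}")
    cols = [table.descriptor_names.index(d) for d in model.descriptor_names]
    X = table.X[:, cols] if indices is None else table.X[np.asarray(indices, int)][:, cols]
    return model.intercept + X @ model.coefficients


def percent_rmse_tr(
    t_obs: np.ndarray, t_pred: np.ndarray, variant: str = "relative_rmse"
) -> float:
    """Percentage relative RMSE of retention time.

    The default variant is 100*sqrt(mean(((pred-obs)/obs)^2)); it is zero iff
    the vectors are identical.  ``signed_mean`` returns the signed relative
    mean error 100*mean((pred-obs)/obs), as printed in the source formula.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    t_pred = np.asarray(t_pred, dtype=float)
    if t_obs.shape != t_pred.shape or t_obs.ndim != 1 or len(t_obs) < 1:
        raise ValidationError("observed and predicted vectors must match, n >= 1")
    if np.any(t_obs <= 0):
        raise ValidationError("observed retention times must be strictly positive")
    rel = (t_pred - t_obs) / t_obs
    if variant == "signed_mean":
        return float(100.0 * rel.mean())
    if variant != "relative_rmse":
        raise ValidationError(f"unknown variant {variant!r}")
    return float(100.0 * np.sqrt(np.mean(rel**2)))


def elution_ranks(t: np.ndarray) -> np.ndarray:
    """1-based elution ranks: position of each analyte in the ascending sort.

    Ties are broken by original row order (stable sort), so the output is
    always a permutation of 1..n.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 1:
        raise ValidationError("rank input must be a non-empty 1-D vector")
    order = np.argsort(t, kind="stable")
    ranks = np.empty(len(t), dtype=int)
    ranks[order] = np.arange(1, len(t) + 1)
    return ranks


def _check_permutation(r: np.ndarray, name: str) -> np.ndarray:
    r = np.asarray(r, dtype=int)
    n = len(r)
    if r.ndim != 1 or not np.array_equal(np.sort(r), np.arange(1, n + 1)):
        raise ValidationError(f"{name} is not a permutation of 1..n")
    return r


def percent_rmse_order(
    obs_ranks: np.ndarray, pred_ranks: np.ndarray, variant: str = "relative_rmse"
) -> float:
    """Percentage relative RMSE of elution order (rank analogue of %RMSE(t_R)).

    Both inputs must be permutations of 1..n.  Division by the observed rank
    weights misordering of early-eluting analytes most heavily; values can
    exceed 100% for badly scrambled orders.
    """
    obs = _check_permutation(obs_ranks, "obs_ranks")
    pred = _check_permutation(pred_ranks, "pred_ranks")
    if len(obs) != len(pred):
        raise ValidationError("rank vectors must have equal length")
    rel = (pred - obs) / obs.astype(float)
    if variant == "signed_mean":
        return float(100.0 * rel.mean())
    if variant != "relative_rmse":
        raise ValidationError(f"unknown variant {variant!r}")
    return float(100.0 * np.sqrt(np.mean(rel**2)))


def evaluate_model(
    model: QSRRModel,
    table: AnalyteTable,
    indices: Sequence[int] | None = None,
    config: CaseStudyConfig | None = None,
) -> tuple[float, float]:
    """Objective pair (f1, f2) = (%RMSE(t_R), %RMSE(order)) on a row subset.

    Elution ranks are computed within the given subset only, so train and
    test metrics are self-contained.
    """
    variant = config.rmse_variant if config is not None else "relative_rmse"
    idx = np.arange(table.n) if indices is None else np.asarray(indices, dtype=int)
    t_obs = table.t_obs[idx]
    t_pred = predict(model, table, idx)
    f1 = percent_rmse_tr(t_obs, t_pred, variant)
    f2 = percent_rmse_order(elution_ranks(t_obs), elution_ranks(t_pred), variant)
    return f1, f2
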