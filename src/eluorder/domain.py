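"""Williams-plot applicability domain: leverages and standardized residuals.

An analyte is inside the model's applicability domain when its leverage
(diagonal element of the hat matrix with respect to the training design) does
not exceed the critical leverage h* and its standardized residual lies within
plus/minus three standard deviations.  The default critical leverage follows
the published convention h* = 3(K-1)/N with K counting the model variables
including the intercept; the more common 3(K+1)/N with K = number of
descriptors is available as an option, and the two coincide in meaning when
K is shifted by the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import AnalyteTable, CaseStudyConfig
from .errors import SingularDesignError, ValidationError
from .qsrr import QSRRModel, SplitResult, design_matrix, predict

__all__ = [
    "ADReport",
    "critical_leverage",
    "leverages",
    "standardized_residuals",
    "williams_report",
]

FLAG_INSIDE = "inside"
FLAG_X = "x_outlier"
FLAG_Y = "y_outlier"
FLAG_XY = "xy_outlier"

_SD_LIMIT = 3.0  # warning limit in multiples of the residual standard deviation


@dataclass(frozen=True)
class ADReport:
    """Williams-plot content for every analyte (training and test rows).

    ``h_star`` is the critical leverage; ``flags[i]`` classifies analyte i as
    inside the domain, a structural (leverage) outlier, a response (residual)
    outlier, or both.
    """

    ids: tuple[str, ...]
    set_label: tuple[str, ...]
    leverages: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    K_used: int
    N_used: int
    flags: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        out = {FLAG_INSIDE: 0, FLAG_X: 0, FLAG_Y: 0, FLAG_XY: 0}
        for f in self.flags:
            out[f] += 1
        return out


def critical_leverage(K: int, N: int, formula: str = "k_minus_1") -> float:
    """Critical (warning) leverage h*.

    ``k_minus_1``: h* = 3(K-1)/N with K = number of model variables
    including the intercept.  ``k_plus_1``: h* = 3(K+1)/N with
    K = number of descriptors.
    """
    if K < 1 or N < 1:
        raise ValidationError("K and N must be positive")
    if formula == "k_minus_1":
        h = 3.0 * (K - 1) / N
        if h == 0.0:
            warnings.warn(
                "critical leverage is 0 for K=1 under the 3(K-1)/N formula; "
                "every analyte with positive leverage will flag as an outlier",
                stacklevel=2,
            )
        return h
    if formula == "k_plus_1":
        return 3.0 * (K + 1) / N
    raise ValidationError(f"unknown leverage formula {formula!r}")


def leverages(train_design: np.ndarray, query_design: np.ndarray) -> np.ndarray:
    """Leverage h_q = x_q' (X'X)^-1 x_q of each query row w.r.t. the training design.

    Training rows evaluated against their own design give the hat-matrix
    diagonal, which lies in (0, 1] and sums to the number of parameters.
    """
    A = np.asarray(train_design, dtype=float)
    Q = np.atleast_2d(np.asarray(query_design, dtype=float))
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularDesignError("training design is rank deficient")
    G = A.T @ A
    # h_q = x_q' G^{-1} x_q via a solve, avoiding the explicit inverse
    sol = np.linalg.solve(G, Q.T)
    return np.einsum("ij,ji->i", Q, sol)


def standardized_residuals(
    residuals: np.ndarray, scale_residuals: np.ndarray | None = None
) -> np.ndarray:
    """Residuals divided by the sample standard deviation of the training residuals.

    ``scale_residuals`` defaults to ``residuals`` itself; pass the training
    residuals when standardizing a test set.  Zero residual variance yields
    an all-zero output with a warning.
    """
    r = np.asarray(residuals, dtype=float)
    base = r if scale_residuals is None else np.asarray(scale_residuals, dtype=float)
    if len(base) < 2:
        raise ValidationError("need at least 2 residuals to estimate a scale")
    sd = float(np.std(base, ddof=1))
    if sd == 0.0:
        warnings.warn("zero residual variance; standardized residuals set to 0",
                      stacklevel=2)
        return np.zeros_like(r)
    return r / sd


def _flag(h: float, sr: float, h_star: float) -> str:
    x_out = h > h_star
    y_out = abs(sr) > _SD_LIMIT
    if x_out and y_out:
        return FLAG_XY
    if x_out:
        return FLAG_X
    if y_out:
        return FLAG_Y
    return FLAG_INSIDE


def williams_report(
    model: QSRRModel,
    table: AnalyteTable,
    split: SplitResult,
    config: CaseStudyConfig | None = None,
) -> ADReport:
    """Leverages, standardized residuals and domain flags for every analyte.

    The hat matrix and the residual scale come from the training rows only;
    test analytes are projected onto the training design.
    """
    formula = config.leverage_formula if config is not None else "k_minus_1"
    train = np.asarray(split.train_indices, dtype=int)
    n_params = table.k + 1
    A_train = design_matrix(table, train)
    A_all = design_matrix(table)
    h_all = leverages(A_train, A_all)

    resid_all = table.t_obs - predict(model, table)
    # An exact fit leaves only rounding noise; standardizing by its "sd"
    # would manufacture spurious residual outliers.
    tol = 1e-9 * max(1.0, float(np.abs(table.t_obs).max()))
    if np.abs(resid_all).max() < tol:
        resid_all = np.zeros_like(resid_all)
    sr_all = standardized_residuals(resid_all, scale_residuals=resid_all[train])

    K_used = n_params  # model variables counted including the intercept
    N_used = len(train)
    h_star = critical_leverage(K_used, N_used, formula)

    labels = ["test"] * table.n
    for i in train:
        labels[i] = "train"
    flags = tuple(_flag(h, sr, h_star) for h, sr in zip(h_all, sr_all))
    return ADReport(
        ids=table.ids,
        set_label=tuple(labels),
        leverages=h_all,
        std_residuals=sr_all,
        h_star=h_star,
        K_used=K_used,
        N_used=N_used,
        flags=flags,
    )
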