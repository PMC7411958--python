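"""Synthetic analyte tables with the statistical structure the method assumes.

The generator emulates the linear QSRR world: K correlated Gaussian
descriptors per analyte and a retention time that is a linear combination of
them plus Gaussian noise, optionally heteroscedastic (noise standard
deviation proportional to the true retention time, emulating the larger
deviations observed at the retention extremes).  Rows whose noisy retention
time is non-positive are redrawn, preserving the linear-Gaussian structure
rather than truncating it.

Two presets mirror the published case-study shapes: 62 organic compounds and
98 synthetic peptides, both with K=3 descriptors, with coefficient and noise
scales chosen so the control MLR model's retention-time error lands in the
published 8-25% range.  What the generator deliberately does not emulate:
real descriptor distributions (which are skewed and collinear in
structure-specific ways), chromatographic nonlinearity at low retention, and
column physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import AnalyteTable, CS1_DESCRIPTORS, CS2_DESCRIPTORS
from .errors import ValidationError
from .moo import ParetoFront, ParetoSolution
from .qsrr import QSRRModel

__all__ = [
    "GeneratorSpec",
    "generate_linear_dataset",
    "preset_cs1_like",
    "preset_cs2_like",
    "generate_front_fixture",
]

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the linear-Gaussian retention generator.

    ``true_coefficients`` is (a0, a1, ..., aK) in minutes (per descriptor
    unit); descriptors are standard normal with pairwise correlation
    ``descriptor_correlation``.  ``noise_sd`` is in minutes; when
    ``heteroscedastic`` the per-row noise sd is scaled by the ratio of the
    row's true retention time to the mean true retention time, keeping the
    average noise level at ``noise_sd``.
    """

    n: int = 80
    K: int = 3
    true_coefficients: tuple[float, ...] = (20.0, 5.0, 2.0, 3.0)
    descriptor_names: tuple[str, ...] | None = None
    descriptor_correlation: float = 0.3
    noise_sd: float = 1.0
    heteroscedastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3 or self.K < 1:
            raise ValidationError("need n >= 3 analytes and K >= 1 descriptors")
        if len(self.true_coefficients) != self.K + 1:
            raise ValidationError(
                f"true_coefficients must have length K+1={self.K + 1}"
            )
        if not 0.0 <= self.descriptor_correlation < 1.0:
            raise ValidationError("descriptor_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.descriptor_names is not None:
            names = tuple(self.descriptor_names)
            if len(names) != self.K:
                raise ValidationError("descriptor_names must have length K")
            object.__setattr__(self, "descriptor_names", names)


def _descriptor_names(spec: GeneratorSpec) -> tuple[str, ...]:
    if spec.descriptor_names is not None:
        return spec.descriptor_names
    return tuple(f"x{j + 1}" for j in range(spec.K))


def generate_linear_dataset(
    spec: GeneratorSpec,
) -> tuple[AnalyteTable, QSRRModel]:
    """Draw a synthetic analyte table; returns it with the generating model.

    The returned :class:`QSRRModel` holds the true coefficients (its
    ``residual_sd`` is the nominal ``noise_sd``), enabling parameter-recovery
    tests.  Rows with non-positive retention are redrawn up to 1000 times.
    """
    rng = np.random.default_rng(spec.seed)
    cov = np.full((spec.K, spec.K), spec.descriptor_correlation)
    np.fill_diagonal(cov, 1.0)
    a0 = spec.true_coefficients[0]
    a = np.asarray(spec.true_coefficients[1:], dtype=float)

    rows_X = np.empty((spec.n, spec.K))
    rows_t = np.empty(spec.n)
    # Mean true retention over the descriptor distribution is a0 (X centered);
    # used as the heteroscedastic scale anchor.
    filled = 0
    for _ in range(_MAX_REDRAWS):
        need = spec.n - filled
        if need == 0:
            break
        X = rng.multivariate_normal(np.zeros(spec.K), cov, size=need,
                                    method="cholesky")
        t_true = a0 + X @ a
        if spec.heteroscedastic:
            sd = spec.noise_sd * np.maximum(t_true, 0.0) / max(a0, 1e-12)
        else:
            sd = np.full(need, spec.noise_sd)
        t = t_true + rng.normal(0.0, 1.0, size=need) * sd
        ok = t > 0
        n_ok = int(ok.sum())
        rows_X[filled : filled + n_ok] = X[ok]
        rows_t[filled : filled + n_ok] = t[ok]
        filled += n_ok
    else:
        if filled < spec.n:
            raise ValidationError(
                "could not generate positive retention times; the coefficient "
                "and noise scales make t_obs <= 0 too likely"
            )

    names = _descriptor_names(spec)
    table = AnalyteTable(
        ids=tuple(f"A{i + 1:03d}" for i in range(spec.n)),
        descriptor_names=names,
        X=rows_X,
        t_obs=rows_t,
    )
    truth = QSRRModel(
        intercept=a0,
        coefficients=a,
        descriptor_names=names,
        n_train=spec.n,
        residual_sd=spec.noise_sd,
    )
    return table, truth


def preset_cs1_like(seed: int = 0, noise_sd: float = 1.3) -> GeneratorSpec:
    """62 analytes, 3 descriptors: the organic-molecules case-study shape.

    Retention times center near 15 min with ~3.5 min structural spread;
    the default 1.3 min homoscedastic noise puts the control model's
    %RMSE(t_R) in the 8-15% region of the published 8-25% band.
    """
    return GeneratorSpec(
        n=62,
        K=3,
        true_coefficients=(15.0, 2.0, 1.5, 2.0),
        descriptor_names=CS1_DESCRIPTORS,
        descriptor_correlation=0.3,
        noise_sd=noise_sd,
        heteroscedastic=False,
        seed=seed,
    )


def preset_cs2_like(seed: int = 0, noise_sd: float = 3.5) -> GeneratorSpec:
    """98 analytes, 3 descriptors: the synthetic-peptides case-study shape.

    Heteroscedastic by default (noise grows with retention), with an average
    noise of 3.5 min on retention times centered near 30 min, giving control
    %RMSE(t_R) around 10-15% and substantial elution-order error, as in the
    published peptide columns.
    """
    return GeneratorSpec(
        n=98,
        K=3,
        true_coefficients=(30.0, 10.0, 3.0, 5.0),
        descriptor_names=CS2_DESCRIPTORS,
        descriptor_correlation=0.4,
        noise_sd=noise_sd,
        heteroscedastic=True,
        seed=seed,
    )


def generate_front_fixture(
    shape: str, size: int = 10, seed: int = 0
) -> ParetoFront:
    """Synthetic Pareto fronts with a known knee, for selection-logic tests.

    ``single_point``: one solution (knee at 0).  ``L_shaped``: for size 3 the
    canonical {(0,1), (0.1,0.1), (1,0)} with the knee at the corner point;
    larger sizes pad the two arms.  ``convex``: points on the convex curve
    f2 = (1 - sqrt(f1))^2 with small jitter on f1 spacing.
    """
    if size < 1:
        raise ValidationError("front size must be >= 1")
    rng = np.random.default_rng(seed)
    zeros = np.zeros(2)
    if shape == "single_point":
        sols = [ParetoSolution(coefficients=zeros, f1=1.0, f2=1.0)]
    elif shape == "L_shaped":
        if size < 3:
            raise ValidationError("an L-shaped front needs at least 3 points")
        if size == 3:
            pts = [(0.0, 1.0), (0.1, 0.1), (1.0, 0.0)]
        else:
            # two arms around the corner (0.1, 0.1), which stays the knee
            n_left = (size - 1) // 2
            n_right = size - 1 - n_left
            left = zip(np.linspace(0.0, 0.08, n_left),
                       np.linspace(1.0, 0.3, n_left))
            right = zip(np.linspace(0.3, 1.0, n_right),
                        np.linspace(0.08, 0.0, n_right))
            pts = [*left, (0.1, 0.1), *right]
        sols = [ParetoSolution(coefficients=zeros, f1=float(a), f2=float(b))
                for a, b in pts]
    elif shape == "convex":
        f1 = np.sort(rng.uniform(0.0, 1.0, size=size))
        f2 = (1.0 - np.sqrt(f1)) ** 2
        sols = [
            ParetoSolution(coefficients=zeros, f1=float(a), f2=float(b))
            for a, b in zip(f1, f2)
        ]
    else:
        raise ValidationError(f"unknown front shape {shape!r}")
    return ParetoFront(solutions=tuple(sols))
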