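"""Domain types, tabular I/O and configuration for QSRR elution-order modelling.

The central container is :class:`AnalyteTable`: one row per analyte with a
unique identifier, K named molecular-descriptor columns and an observed
gradient retention time in minutes.  All downstream stages (regression,
multi-objective re-optimization, applicability domain, ranking) operate on
this table; row order is significant because elution ranks are tied to row
indexing and is therefore never permuted by I/O.

Two descriptor presets mirror the published case studies: small organic
molecules described by total dipole moment, most-negative atomic charge and
solvent-accessible surface area; and synthetic peptides described by the
log-sum of amino-acid gradient retention times, clogP and the log van der
Waals volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError, ValidationError

__all__ = [
    "AnalyteTable",
    "CaseStudyConfig",
    "GAParams",
    "CS1_DESCRIPTORS",
    "CS2_DESCRIPTORS",
    "cs1_config",
    "cs2_config",
    "read_analyte_table",
    "write_analyte_table",
    "read_config",
    "write_config",
    "validate_config",
]

#: Descriptor presets of the two case studies (any column order is accepted).
CS1_DESCRIPTORS = ("mu", "delta_min", "SASA")
CS2_DESCRIPTORS = ("logSumAA", "clogP", "log_vdW_vol")


@dataclass(frozen=True)
class AnalyteTable:
    """Validated analyte table: IDs, descriptor matrix, retention times.

    Parameters
    ----------
    ids:
        Unique analyte identifiers, one per row.
    descriptor_names:
        Names of the K descriptor columns of ``X``.
    X:
        ``(n, K)`` array of finite descriptor values, in the units provided.
    t_obs:
        Observed gradient retention times in minutes; strictly positive
        (relative errors divide by the observed values).
    set_label:
        Optional per-row tag in ``{"train", "test", "unassigned"}``.
    """

    ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    X: np.ndarray
    t_obs: np.ndarray
    set_label: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        t = np.asarray(self.t_obs, dtype=float)
        if X.ndim != 2:
            raise ValidationError("descriptor matrix X must be 2-D")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "t_obs", t)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(
            self, "descriptor_names", tuple(str(d) for d in self.descriptor_names)
        )
        n, k = X.shape
        if k < 1:
            raise ValidationError("at least one descriptor column is required")
        if len(self.descriptor_names) != k:
            raise ValidationError(
                f"{len(self.descriptor_names)} descriptor names for {k} columns"
            )
        if len(self.ids) != n or t.shape != (n,):
            raise ValidationError("ids, X and t_obs must have matching length")
        if len(set(self.ids)) != n:
            raise ValidationError("analyte ids must be unique")
        if not np.all(np.isfinite(X)):
            bad = int(np.where(~np.isfinite(X).all(axis=1))[0][0])
            raise ValidationError(f"non-finite descriptor value in row {bad}")
        if not np.all(np.isfinite(t)):
            bad = int(np.where(~np.isfinite(t))[0][0])
            raise ValidationError(f"non-finite retention time in row {bad}")
        if n and np.any(t <= 0):
            bad = int(np.where(t <= 0)[0][0])
            raise ValidationError(
                f"retention time must be strictly positive; row {bad} "
                f"(id={self.ids[bad]!r}) has t_obs={t[bad]}"
            )
        if self.set_label is not None:
            labels = tuple(self.set_label)
            if len(labels) != n:
                raise ValidationError("set_label length must equal n")
            bad_labels = set(labels) - {"train", "test", "unassigned"}
            if bad_labels:
                raise ValidationError(f"unknown set labels: {sorted(bad_labels)}")
            object.__setattr__(self, "set_label", labels)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def with_labels(self, train: Sequence[int], test: Sequence[int]) -> "AnalyteTable":
        """Return a copy tagged with train/test labels for the given rows."""
        labels = ["unassigned"] * self.n
        for i in train:
            labels[int(i)] = "train"
        for i in test:
            labels[int(i)] = "test"
        return dataclasses.replace(self, set_label=tuple(labels))

    def to_frame(self, id_column: str = "id", rt_column: str = "tR") -> pd.DataFrame:
        data: dict[str, object] = {id_column: list(self.ids)}
        for j, name in enumerate(self.descriptor_names):
            data[name] = self.X[:, j]
        data[rt_column] = self.t_obs
        if self.set_label is not None:
            data["set_label"] = list(self.set_label)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class GAParams:
    """Hyperparameters of the multi-objective genetic search.

    The published method specifies only that a genetic algorithm seeded at
    the MLR coefficients is used; population size, generation count and
    variation operators are implementation choices (see the methods note).

    ``init_spread`` is the relative scale of the Gaussian perturbations used
    to seed the initial population around the MLR coefficient vector.
    """

    population_size: int = 100
    generations: int = 200
    crossover_prob: float = 0.9
    mutation_prob: float = 0.2
    init_spread: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ConfigurationError("population_size must be >= 4")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.init_spread <= 0:
            raise ConfigurationError("init_spread must be positive")


@dataclass(frozen=True)
class CaseStudyConfig:
    """Run configuration: schema, split ratio, optimizer and metric variants.

    ``max_tr_loss_percent`` is the user bound on the acceptable relative
    increase of the retention-time error over the MLR control when selecting
    a compromise solution from the Pareto front (the published case studies
    used ~5-10%).
    """

    descriptor_names: tuple[str, ...]
    id_column: str = "id"
    rt_column: str = "tR"
    split_ratio: float = 0.70
    ga_params: GAParams = field(default_factory=GAParams)
    max_tr_loss_percent: float = 10.0
    rmse_variant: str = "relative_rmse"  # or "signed_mean" (audit only)
    srd_mode: str = "absolute"  # or "squared"
    leverage_formula: str = "k_minus_1"  # or "k_plus_1"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "descriptor_names", tuple(str(d) for d in self.descriptor_names)
        )
        if not self.descriptor_names:
            raise ConfigurationError("descriptor_names must be non-empty")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigurationError("split_ratio must be in (0, 1)")
        if self.max_tr_loss_percent < 0:
            raise ConfigurationError("max_tr_loss_percent must be >= 0")
        if self.rmse_variant not in ("relative_rmse", "signed_mean"):
            raise ConfigurationError(f"unknown rmse_variant {self.rmse_variant!r}")
        if self.srd_mode not in ("absolute", "squared"):
            raise ConfigurationError(f"unknown srd_mode {self.srd_mode!r}")
        if self.leverage_formula not in ("k_minus_1", "k_plus_1"):
            raise ConfigurationError(
                f"unknown leverage_formula {self.leverage_formula!r}"
            )


def cs1_config(**overrides) -> CaseStudyConfig:
    """Configuration preset for the organic-molecules case study (K=3)."""
    return CaseStudyConfig(descriptor_names=CS1_DESCRIPTORS, **overrides)


def cs2_config(**overrides) -> CaseStudyConfig:
    """Configuration preset for the synthetic-peptides case study (K=3)."""
    return CaseStudyConfig(descriptor_names=CS2_DESCRIPTORS, **overrides)


def validate_config(config: CaseStudyConfig) -> list[str]:
    """Return warnings for non-default metric/formula variants.

    Construction already enforces the hard invariants; this reports soft
    deviations from the published defaults so runs are auditable.
    """
    warnings: list[str] = []
    if config.rmse_variant == "signed_mean":
        warnings.append(
            "rmse_variant=signed_mean computes a signed relative mean error "
            "without squaring or root; it can be negative and is kept for "
            "auditing only."
        )
    if config.srd_mode == "squared":
        warnings.append(
            "srd_mode=squared uses squared rank differences; the published "
            "random-ranking statistics match the absolute (footrule) mode."
        )
    if config.leverage_formula == "k_plus_1":
        warnings.append(
            "leverage_formula=k_plus_1 uses h* = 3(K+1)/N with "
            "K = number of descriptors, instead of the published 3(K-1)/N "
            "with K counting the intercept."
        )
    return warnings


def read_analyte_table(path: str | Path, config: CaseStudyConfig) -> AnalyteTable:
    """Read a CSV analyte table, validating schema and invariants.

    The header must contain ``config.id_column``, every configured descriptor
    column and ``config.rt_column``; any column order is accepted and row
    order is preserved exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = [config.id_column, *config.descriptor_names, config.rt_column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in (*config.descriptor_names, config.rt_column):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            raise ValidationError(
                f"{path.name}: non-numeric or missing value in column "
                f"{col!r}, row {int(bad[0])}"
            )
    labels = (
        tuple(df["set_label"].astype(str)) if "set_label" in df.columns else None
    )
    return AnalyteTable(
        ids=tuple(df[config.id_column].astype(str)),
        descriptor_names=config.descriptor_names,
        X=df[list(config.descriptor_names)].to_numpy(dtype=float),
        t_obs=df[config.rt_column].to_numpy(dtype=float),
        set_label=labels,
    )


def write_analyte_table(
    table: AnalyteTable,
    path: str | Path,
    id_column: str = "id",
    rt_column: str = "tR",
) -> None:
    """Write the table as CSV; reading it back reproduces it exactly.

    Floats are written at full round-trip precision.
    """
    table.to_frame(id_column=id_column, rt_column=rt_column).to_csv(
        path, index=False
    )


def _config_to_dict(config: CaseStudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["descriptor_names"] = list(config.descriptor_names)
    return d


def write_config(config: CaseStudyConfig, path: str | Path) -> None:
    """Serialize the configuration as a flat YAML document."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def read_config(path: str | Path) -> CaseStudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ga = raw.pop("ga_params", None)
    if ga is not None:
        raw["ga_params"] = GAParams(**ga)
    raw["descriptor_names"] = tuple(raw["descriptor_names"])
    return CaseStudyConfig(**raw)
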