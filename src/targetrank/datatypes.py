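"""Core data containers for the target-prioritization pipeline.

Gene symbols are uppercase HGNC-style strings and are the join key
everywhere; no alias resolution is attempted. Expression matrices,
feature matrices and reports are pandas DataFrames indexed by gene.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input object violates its contract."""


class ConfigError(ValidationError):
    """Raised for malformed project-parameter files."""


#: the four enrichment categories plus the user-dataset category
CATEGORIES = (
    "tumor_expression",
    "normal_expression",
    "localization",
    "annotation",
    "therapeutic",
)

RESCALE_METHODS = ("rank_percentile", "minmax")
IMPUTE_METHODS = ("zero", "neutral", "min", "median")

DEFAULT_WEIGHT_BOUNDS = (-10.0, 10.0)
DEFAULT_CURVE_BOUNDS = (-3.0, 3.0)


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with phenotype metadata.

    ``values`` holds one row per gene (uppercase, unique symbols) and one
    column per sample. Missing cells are NaN and are allowed; they
    propagate into missing summary statistics downstream.
    """

    values: pd.DataFrame
    phenotype: str = ""
    units: str = "linear"  # "linear" or "log2"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index.astype(str).str.upper()
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(
                f"duplicate gene symbols after uppercasing: {dups[:5]}"
            )
        if self.values.shape[1] == 0:
            raise ValidationError("expression dataset has zero samples")
        if self.units not in ("linear", "log2"):
            raise ValidationError(f"unknown units {self.units!r}")
        self.values = self.values.copy()
        self.values.index = idx

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FeatureSpec:
    """Description and transform parameters for one scoring feature.

    ``direction`` folds into the default weight sign: ``lower_better``
    features start at weight -1 so that e.g. high normal-tissue
    expression penalizes a candidate. ``source`` resolves the feature's
    values: ``summary:<col>`` (user-dataset summary statistic),
    ``snapshot:<name>:<col>`` (a snapshot column verbatim), or
    ``derived:<rule>`` (a documented derivation such as the max across
    normal-tissue columns).
    """

    name: str
    category: str
    source: str
    direction: str = "higher_better"
    rescale_method: str = "rank_percentile"
    impute_method: str = "neutral"
    weight: float | None = None
    curve: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.rescale_method not in RESCALE_METHODS:
            raise ValidationError(f"unknown rescale method {self.rescale_method!r}")
        if self.impute_method not in IMPUTE_METHODS:
            raise ValidationError(f"unknown impute method {self.impute_method!r}")
        if self.weight is None:
            self.weight = 1.0 if self.direction == "higher_better" else -1.0
        if not np.isfinite(self.weight) or not np.isfinite(self.curve):
            raise ValidationError("weight and curve must be finite")


@dataclass
class FeatureSnapshot:
    """A database snapshot table keyed by gene symbol.

    ``table`` is indexed by unique uppercase gene symbols for gene-keyed
    schemas; record-style schemas (drug tables) keep one row per record
    with the gene in a column.
    """

    source_name: str
    table: pd.DataFrame
    schema: str = ""
    version: str = ""


@dataclass
class FeatureMatrix:
    """Genes x features matrix aligned to a dataset's gene list.

    Rows correspond to the dataset's genes (never the snapshot's);
    missing values mark genes absent from a snapshot and are resolved by
    the impute stage, not here.
    """

    values: pd.DataFrame
    catalog: list[FeatureSpec]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.catalog]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names in catalog")
        enabled = [s.name for s in self.catalog if s.enabled]
        missing = [n for n in enabled if n not in self.values.columns]
        if missing:
            raise ValidationError(f"matrix lacks enabled feature columns {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.catalog:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class LabelSet:
    """Known-positive and known-negative target genes for one phenotype."""

    positives: frozenset[str]
    negatives: frozenset[str] = frozenset()
    phenotype: str = ""
    provenance: str = "user_list"

    def __post_init__(self) -> None:
        self.positives = frozenset(g.upper() for g in self.positives)
        self.negatives = frozenset(g.upper() for g in self.negatives)
        overlap = self.positives & self.negatives
        if overlap:
            raise ValidationError(
                f"genes labeled both positive and negative: {sorted(overlap)[:5]}"
            )


@dataclass
class ScoreReport:
    """Per-gene feature values, transformed contributions, and final score.

    ``table`` is indexed by gene, sorted by rank; ``<f>`` columns carry
    the enriched raw values, ``<f>__transformed`` the weighted curved
    contribution (so ``score`` equals the row-sum of transformed
    columns), plus ``score``, ``rank`` (1 = best) and ``percentile``
    (100 = best). MAP is attached when labels were available.
    """

    table: pd.DataFrame
    map_score: float | None = None
    map_mode: str | None = None

    def __post_init__(self) -> None:
        t = self.table
        for col in ("score", "rank", "percentile"):
            if len(t) and col not in t.columns:
                raise ValidationError(f"report missing column {col!r}")
        if len(t):
            ranks = np.sort(t["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(1, len(t) + 1)):
                raise ValidationError("ranks are not a permutation of 1..n")
            ordered = t.sort_values("rank")["score"].to_numpy()
            if np.any(np.diff(ordered) > 1e-12):
                raise ValidationError("score must be non-increasing in rank")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def ranking(self) -> list[str]:
        """Genes ordered best-first."""
        return list(self.table.sort_values("rank").index)


@dataclass
class EvaluationResult:
    """Average precision of one ranking against one label set."""

    map: float
    per_positive: list[tuple[str, int, float]]  # (gene, rank, precision@rank)
    mode: str
    n_positives: int
    n_negatives: int


@dataclass
class ParamVector:
    """Ordered (feature, weight, curve) triples with box bounds."""

    features: list[str]
    weights: np.ndarray
    curves: np.ndarray
    weight_bounds: tuple[float, float] = DEFAULT_WEIGHT_BOUNDS
    curve_bounds: tuple[float, float] = DEFAULT_CURVE_BOUNDS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if len(self.features) != len(self.weights) or len(self.features) != len(
            self.curves
        ):
            raise ValidationError("features, weights and curves must align")
        lo, hi = self.weight_bounds
        if np.any(self.weights < lo) or np.any(self.weights > hi):
            raise ValidationError("weight outside bounds")
        lo, hi = self.curve_bounds
        if np.any(self.curves < lo) or np.any(self.curves > hi):
            raise ValidationError("curve outside bounds")

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.weights, self.curves])

    def with_array(self, x: np.ndarray) -> "ParamVector":
        k = len(self.features)
        return ParamVector(
            list(self.features),
            np.asarray(x[:k], dtype=float),
            np.asarray(x[k:], dtype=float),
            self.weight_bounds,
            self.curve_bounds,
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        k = len(self.features)
        lo = np.concatenate(
            [np.full(k, self.weight_bounds[0]), np.full(k, self.curve_bounds[0])]
        )
        hi = np.concatenate(
            [np.full(k, self.weight_bounds[1]), np.full(k, self.curve_bounds[1])]
        )
        return lo, hi

    def as_mapping(self) -> dict[str, dict[str, float]]:
        return {
            f: {"weight": float(w), "curve": float(c)}
            for f, w, c in zip(self.features, self.weights, self.curves)
        }


@dataclass
class OptimizationResult:
    """Outcome of one optimization stage or of the full pipeline."""

    params: ParamVector
    selected: list[str]
    trace: list[float]
    initial_map: float
    final_map: float
    strategy: str = "multi_cancer"
    seed: int | None = None
    method_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trace and any(
            b < a - 1e-12 for a, b in zip(self.trace, self.trace[1:])
        ):
            raise ValidationError("best-so-far trace must be non-decreasing")
        if self.final_map < self.initial_map - 1e-12:
            raise ValidationError("final MAP below initial MAP")
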