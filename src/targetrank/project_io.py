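"""Reading expression datasets and project parameters; writing reports.

Expression input is TSV/CSV (genes in rows, header row of sample ids,
first column gene symbols) or GCT v1.2. Numbers always use '.' as the
decimal separator regardless of locale. Non-numeric cells become
missing; duplicate symbols collapse by a configurable aggregation
(element-wise max by default, conservative for a high-expression
criterion).
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ConfigError,
    DEFAULT_CURVE_BOUNDS,
    DEFAULT_WEIGHT_BOUNDS,
    ExpressionDataset,
    ScoreReport,
    ValidationError,
)

logger = logging.getLogger("targetrank")

__all__ = [
    "read_expression",
    "summarize_genes",
    "write_report",
    "read_report",
    "ProjectConfig",
    "load_config",
    "DEFAULT_STATS",
]

DEFAULT_STATS = ("mean", "median", "max", "q75", "frac_expressed(0)")


# ---------------------------------------------------------------- expression

def _infer_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("tsv", "txt"):
        return "tsv"
    if ext in ("csv", "gct"):
        return ext
    raise ValidationError(f"cannot infer format from extension {ext!r}")


def _aggregate_duplicates(df: pd.DataFrame, how: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    dups = sorted(df.index[df.index.duplicated()].unique())
    if how == "error":
        raise ValidationError(f"duplicate gene symbols {dups[:5]} (aggregation disabled)")
    if how not in ("max", "mean"):
        raise ValidationError(f"unknown aggregation policy {how!r}")
    logger.warning("collapsing %d duplicate symbols by %s: %s", len(dups), how, dups[:5])
    return df.groupby(level=0, sort=False).agg(how)


def read_expression(
    path: str | Path,
    format: str | None = None,
    units: str = "linear",
    phenotype: str = "",
    aggregate: str = "max",
) -> ExpressionDataset:
    """Read a genes x samples expression table into an ExpressionDataset.

    Gene symbols are uppercased; duplicates collapse element-wise by
    ``aggregate`` ({"max", "mean", "error"}). Non-numeric cells become
    NaN; all-missing gene rows are kept with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
    elif fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValidationError(f"unsupported GCT version line {version!r}")
            fh.readline()  # dimension line; shape is validated from the body
            df = pd.read_csv(fh, sep="\t", index_col=0)
        # GCT carries a Description column between Name and the samples
        if df.columns[:1].tolist() == ["Description"]:
            df = df.drop(columns=["Description"])
    else:
        raise ValidationError(f"unknown format {fmt!r}")

    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str).str.upper()
    df = _aggregate_duplicates(df, aggregate)
    all_missing = df.index[df.isna().all(axis=1)]
    if len(all_missing):
        logger.warning("%d gene rows are entirely missing: %s",
                       len(all_missing), list(all_missing[:5]))
    return ExpressionDataset(values=df, phenotype=phenotype, units=units,
                             metadata={"source": str(path), "units": units})


# ------------------------------------------------------------------ summaries

_FRAC_RE = re.compile(r"^frac_expressed(?:\((?P<thr>[-+0-9.eE]+)\))?$")


def summarize_genes(ds: ExpressionDataset, stats: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Per-gene summary statistics over non-missing samples.

    ``stats`` may contain mean, median, max, min, q25, q75 and
    frac_expressed(threshold) (fraction of samples strictly above the
    threshold; default threshold 0). Genes with all samples missing get
    missing statistics. Output is invariant to sample column order and
    columns are named by the bare statistic (``frac_expressed``
    regardless of threshold).
    """
    if not stats:
        raise ValidationError("empty summary-statistic list")
    v = ds.values
    out = {}
    for stat in stats:
        m = _FRAC_RE.match(stat)
        if m:
            thr = float(m.group("thr")) if m.group("thr") is not None else 0.0
            nonmiss = v.notna().sum(axis=1)
            col = (v > thr).sum(axis=1) / nonmiss.where(nonmiss > 0)
            out["frac_expressed"] = col
        elif stat == "mean":
            out[stat] = v.mean(axis=1)
        elif stat == "median":
            out[stat] = v.median(axis=1)
        elif stat == "max":
            out[stat] = v.max(axis=1)
        elif stat == "min":
            out[stat] = v.min(axis=1)
        elif stat == "q25":
            out[stat] = v.quantile(0.25, axis=1)
        elif stat == "q75":
            out[stat] = v.quantile(0.75, axis=1)
        else:
            raise ValidationError(f"unknown summary statistic {stat!r}")
    return pd.DataFrame(out, index=v.index)


# -------------------------------------------------------------------- reports

def write_report(report: ScoreReport, path: str | Path, format: str = "tsv") -> None:
    """Write a score report as TSV or JSON; round-trips losslessly."""
    path = Path(path)
    if format == "tsv":
        report.table.to_csv(path, sep="\t", index_label="gene")
    elif format == "json":
        payload = {
            "genes": {
                g: {k: (None if pd.isna(val) else val) for k, val in row.items()}
                for g, row in report.table.to_dict(orient="index").items()
            },
            "columns": list(report.table.columns),
            "map": report.map_score,
            "map_mode": report.map_mode,
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValidationError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str | None = None) -> ScoreReport:
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "tsv")
    if fmt == "tsv":
        table = pd.read_csv(path, sep="\t", index_col="gene")
        return ScoreReport(table=table)
    payload = json.loads(path.read_text())
    table = pd.DataFrame.from_dict(payload["genes"], orient="index")
    if len(table):
        table = table[payload["columns"]]
    return ScoreReport(table=table, map_score=payload.get("map"),
                       map_mode=payload.get("map_mode"))


# --------------------------------------------------------------------- config

@dataclass
class DatasetConfig:
    path: str
    phenotype: str = ""
    format: str | None = None
    units: str = "linear"
    aggregate: str = "max"


@dataclass
class SnapshotConfig:
    path: str
    schema: str


@dataclass
class LabelConfig:
    source: str = "drug_snapshot"  # or "explicit"
    positives: dict[str, list[str]] = field(default_factory=dict)  # phenotype -> genes
    negatives: dict[str, list[str]] = field(default_factory=dict)
    modalities: list[str] | None = None


@dataclass
class OptimizationConfig:
    strategy: str = "multi_cancer"
    sfs_threshold: float = 1e-4
    nm_threshold: float = 1e-3
    ga_population: int = 40
    ga_generations: int = 60
    weight_bounds: tuple[float, float] = DEFAULT_WEIGHT_BOUNDS
    curve_bounds: tuple[float, float] = DEFAULT_CURVE_BOUNDS

    def __post_init__(self) -> None:
        if self.sfs_threshold < 0 or self.nm_threshold < 0:
            raise ConfigError("improvement thresholds must be nonnegative fractions")
        for lo, hi in (self.weight_bounds, self.curve_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= 0.0 <= hi):
                raise ConfigError("bounds must be finite intervals containing 0")
        if self.strategy not in ("multi_cancer", "phenotype_specific"):
            raise ConfigError(f"unknown strategy {self.strategy!r}")


@dataclass
class ProjectConfig:
    """In-memory form of the project-parameters YAML."""

    datasets: list[DatasetConfig]
    snapshots: dict[str, SnapshotConfig] = field(default_factory=dict)
    features: dict[str, dict] = field(default_factory=dict)  # per-feature overrides
    labels: LabelConfig = field(default_factory=LabelConfig)
    optimization: OptimizationConfig = field(default_factory=OptimizationConfig)
    stats: list[str] = field(default_factory=lambda: list(DEFAULT_STATS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ConfigError("at least one dataset is required")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed must be a nonnegative integer")


def _build(cls, raw: dict, where: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"{where}: expected a mapping")
    allowed = set(cls.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    try:
        return cls(**{k: tuple(v) if k.endswith("_bounds") else v for k, v in raw.items()})
    except TypeError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def load_config(path: str | Path) -> ProjectConfig:
    """Load and validate a project-parameters YAML file.

    Unknown keys anywhere in the document are an error (catches typos).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("project file must contain a single YAML mapping")
    allowed = set(ProjectConfig.__dataclass_fields__)
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    datasets = [_build(DatasetConfig, d, f"datasets[{i}]")
                for i, d in enumerate(raw.get("datasets", []))]
    snapshots = {name: _build(SnapshotConfig, s, f"snapshots.{name}")
                 for name, s in (raw.get("snapshots") or {}).items()}
    labels = _build(LabelConfig, raw.get("labels") or {}, "labels")
    optimization = _build(OptimizationConfig, raw.get("optimization") or {},
                          "optimization")
    features = raw.get("features") or {}
    known_overrides = {"weight", "curve", "enabled", "rescale_method",
                       "impute_method"}
    for fname, over in features.items():
        bad = set(over) - known_overrides
        if bad:
            raise ConfigError(f"features.{fname}: unknown keys {sorted(bad)}")
    return ProjectConfig(
        datasets=datasets,
        snapshots=snapshots,
        features=features,
        labels=labels,
        optimization=optimization,
        stats=list(raw.get("stats", DEFAULT_STATS)),
        seed=raw.get("seed", 0),
    )
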