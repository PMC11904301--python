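"""Join gene summaries with database-snapshot features; derive labels.

Snapshots are TSV tables keyed by gene symbol, standing in for the
public resources a practitioner would export (normal-tissue expression,
surface-localization evidence, dependency screens, drug/reagent
records). Enrichment is a left join on the *dataset's* genes: a gene
absent from a snapshot gets a missing value, never zero — absence of
evidence must stay distinguishable from a measured zero, and the impute
stage decides the fill.

Percentiles everywhere use linear interpolation between closest ranks
(numpy's default), stated once here and used consistently by the
rescaling and the restricted normal-tissue filter.
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionDataset,
    FeatureMatrix,
    FeatureSnapshot,
    FeatureSpec,
    LabelSet,
    ScoreReport,
    ValidationError,
)
from .project_io import DEFAULT_STATS, summarize_genes

logger = logging.getLogger("targetrank")

__all__ = [
    "load_schema",
    "load_snapshot",
    "default_catalog",
    "enrich",
    "derive_labels",
    "restricted_normal_filter",
    "build_feature_matrix",
]

DRUG_STATUSES = ("approved", "clinical", "discontinued")
DRUG_MODALITIES = ("ADC", "CAR-T", "mAb", "other")


def load_schema(name: str) -> dict:
    """Load a registered snapshot schema shipped with the package."""
    ref = resources.files("targetrank").joinpath(f"schemas/{name}.yaml")
    try:
        return yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise ValidationError(f"unknown snapshot schema {name!r}") from None


def load_snapshot(path: str | Path, schema_name: str) -> FeatureSnapshot:
    """Read and validate a snapshot TSV against a registered schema.

    Gene-keyed schemas collapse duplicate symbols element-wise by max
    (with a warning); record-style schemas (drug tables) keep every row.
    """
    schema = load_schema(schema_name)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValidationError(f"empty snapshot table: {path}")
    key = schema["key_column"]
    first = df.columns[0]
    df = df.rename(columns={first: key})
    missing = [c for c in schema["required_columns"] if c not in df.columns]
    if missing:
        raise ValidationError(
            f"snapshot {path} missing required columns {missing} for schema {schema_name}"
        )
    df[key] = df[key].astype(str).str.upper()
    if schema["kind"] == "record_table":
        table = df
    else:
        table = df.set_index(key)
        table = table.apply(pd.to_numeric, errors="coerce")
        if table.shape[1] < schema.get("min_numeric_columns", 1):
            raise ValidationError(f"snapshot {path} has no numeric columns")
        if table.index.has_duplicates:
            dups = sorted(table.index[table.index.duplicated()].unique())
            logger.warning("snapshot %s: collapsing duplicate symbols by max: %s",
                           schema_name, dups[:5])
            table = table.groupby(level=0, sort=False).max()
    return FeatureSnapshot(source_name=schema_name, table=table, schema=schema_name)


# ------------------------------------------------------------------- catalog

def default_catalog() -> list[FeatureSpec]:
    """Representative default feature catalog across all five categories.

    Twelve features: five summary statistics of the user's tumor
    expression data, two normal-tissue specificity features, one
    surface-localization evidence score, one phenotype-matched
    dependency feature, and three reagent/therapeutic-availability
    flags. Users extend or override the catalog in the project file.
    """
    spec = FeatureSpec
    return [
        spec("expr_mean", "tumor_expression", "summary:mean",
             impute_method="min"),
        spec("expr_median", "tumor_expression", "summary:median",
             impute_method="min"),
        spec("expr_max", "tumor_expression", "summary:max",
             impute_method="min"),
        spec("expr_q75", "tumor_expression", "summary:q75",
             impute_method="min"),
        spec("expr_frac_expressed", "tumor_expression", "summary:frac_expressed",
             rescale_method="minmax", impute_method="min"),
        spec("normal_expr_max", "normal_expression", "derived:normal_expr_max",
             direction="lower_better", impute_method="neutral"),
        spec("normal_expr_pctile", "normal_expression", "derived:normal_expr_pctile",
             direction="lower_better", rescale_method="minmax",
             impute_method="neutral"),
        spec("surface_evidence", "localization", "snapshot:surface_evidence:evidence_score",
             rescale_method="minmax", impute_method="zero"),
        spec("dependency_mean", "annotation", "derived:dependency_mean",
             impute_method="neutral"),
        spec("has_drug", "therapeutic", "derived:has_drug",
             rescale_method="minmax", impute_method="zero"),
        spec("has_adc", "therapeutic", "derived:has_adc",
             rescale_method="minmax", impute_method="zero"),
        spec("pmtl_flag", "therapeutic", "snapshot:pmtl_like:pmtl",
             rescale_method="minmax", impute_method="zero"),
    ]


def apply_overrides(catalog: list[FeatureSpec], overrides: Mapping[str, dict]) -> list[FeatureSpec]:
    """Apply per-feature config overrides (weight/curve/enabled/methods)."""
    by_name = {s.name: s for s in catalog}
    unknown = set(overrides) - set(by_name)
    if unknown:
        raise ValidationError(f"overrides for unknown features {sorted(unknown)}")
    out = []
    for s in catalog:
        over = overrides.get(s.name, {})
        out.append(FeatureSpec(
            name=s.name, category=s.category, source=s.source,
            direction=s.direction,
            rescale_method=over.get("rescale_method", s.rescale_method),
            impute_method=over.get("impute_method", s.impute_method),
            weight=over.get("weight", s.weight),
            curve=over.get("curve", s.curve),
            enabled=over.get("enabled", s.enabled),
        ))
    return out


# -------------------------------------------------------------------- enrich

def _find_snapshot(snapshots: Mapping[str, FeatureSnapshot], schema: str) -> FeatureSnapshot:
    for snap in snapshots.values():
        if snap.schema == schema or snap.source_name == schema:
            return snap
    raise ValidationError(f"no snapshot with schema {schema!r} supplied")


def _percentile_of(dist: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Percentile rank (mean of strict/weak definitions) of each value in dist."""
    dist = np.sort(dist[~np.isnan(dist)])
    n = len(dist)
    lo = np.searchsorted(dist, values, side="left")
    hi = np.searchsorted(dist, values, side="right")
    out = 100.0 * (lo + hi) / (2.0 * n)
    out[np.isnan(values)] = np.nan
    return out


def _resolve(spec: FeatureSpec, genes: pd.Index, summary: pd.DataFrame,
             snapshots: Mapping[str, FeatureSnapshot], phenotype: str) -> tuple[pd.Series, str]:
    kind, _, rest = spec.source.partition(":")
    if kind == "summary":
        if rest not in summary.columns:
            raise ValidationError(
                f"feature {spec.name}: summary column {rest!r} not computed")
        return summary[rest].reindex(genes), "user_dataset"
    if kind == "snapshot":
        schema, _, col = rest.partition(":")
        snap = _find_snapshot(snapshots, schema)
        if col not in snap.table.columns:
            raise ValidationError(
                f"feature {spec.name}: snapshot {schema} lacks column {col!r}")
        return snap.table[col].reindex(genes), snap.source_name
    if kind != "derived":
        raise ValidationError(f"feature {spec.name}: bad source {spec.source!r}")

    rule = rest
    if rule == "normal_expr_max":
        snap = _find_snapshot(snapshots, "gtex_like")
        return snap.table.max(axis=1).reindex(genes), snap.source_name
    if rule == "normal_expr_pctile":
        snap = _find_snapshot(snapshots, "gtex_like")
        per_gene_max = snap.table.max(axis=1)
        vals = per_gene_max.reindex(genes).to_numpy(dtype=float)
        pct = _percentile_of(per_gene_max.to_numpy(dtype=float), vals)
        return pd.Series(pct, index=genes), snap.source_name
    if rule == "dependency_mean":
        snap = _find_snapshot(snapshots, "depmap_like")
        pheno = (phenotype or "").casefold()
        cols = [c for c in snap.table.columns
                if c.partition(".")[0].casefold() == pheno]
        sub = snap.table[cols] if cols else snap.table
        return sub.mean(axis=1).reindex(genes), snap.source_name
    if rule in ("has_drug", "has_adc"):
        snap = _find_snapshot(snapshots, "drugdb")
        rec = snap.table
        covered = pd.Index(rec["gene"].unique())
        if rule == "has_drug":
            flagged = covered
        else:
            flagged = pd.Index(rec.loc[rec["modality"] == "ADC", "gene"].unique())
        col = pd.Series(np.nan, index=genes, dtype=float)
        col[genes.isin(covered)] = 0.0
        col[genes.isin(flagged)] = 1.0
        return col, snap.source_name
    raise ValidationError(f"feature {spec.name}: unknown derivation {rule!r}")


def enrich(
    summary_table: pd.DataFrame,
    snapshots: Mapping[str, FeatureSnapshot],
    catalog: list[FeatureSpec] | None = None,
    phenotype: str = "",
) -> FeatureMatrix:
    """Build the genes x features matrix for the dataset's gene list.

    Left-joins every enabled catalog feature onto the summary table's
    genes; rows are never dropped or reordered and the result does not
    depend on the order snapshots were supplied in.
    """
    catalog = catalog if catalog is not None else default_catalog()
    genes = summary_table.index
    cols: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    for spec in catalog:
        if not spec.enabled:
            continue
        col, source = _resolve(spec, genes, summary_table, snapshots, phenotype)
        cols[spec.name] = col.astype(float)
        provenance[spec.name] = source
    values = pd.DataFrame(cols, index=genes)
    return FeatureMatrix(values=values, catalog=list(catalog), provenance=provenance)


def build_feature_matrix(
    dataset: ExpressionDataset,
    snapshots: Mapping[str, FeatureSnapshot],
    catalog: list[FeatureSpec] | None = None,
    stats: Sequence[str] = DEFAULT_STATS,
) -> FeatureMatrix:
    """Summarize the expression dataset and enrich with snapshot features."""
    summary = summarize_genes(dataset, list(stats))
    return enrich(summary, snapshots, catalog, phenotype=dataset.phenotype)


# -------------------------------------------------------------------- labels

def derive_labels(
    phenotype: str,
    drug_snapshot: FeatureSnapshot,
    modalities: Sequence[str] | None = None,
) -> LabelSet:
    """Known positives/negatives for a phenotype from drug records.

    Positives are genes with at least one approved or clinical-stage
    record matching the phenotype (and modality filter, if given);
    negatives are genes whose phenotype-matching records are *all*
    discontinued. A gene with both active and discontinued records is
    positive. Phenotype matching is exact after case-folding.
    """
    rec = drug_snapshot.table
    bad = set(rec["status"].unique()) - set(DRUG_STATUSES)
    if bad:
        raise ValidationError(f"unknown drug status values {sorted(bad)}")
    sel = rec[rec["phenotype"].astype(str).str.casefold() == phenotype.casefold()]
    if modalities is not None:
        sel = sel[sel["modality"].isin(list(modalities))]
    active = sel["status"].isin(["approved", "clinical"])
    positives = set(sel.loc[active, "gene"])
    negatives = set(sel["gene"]) - positives
    return LabelSet(positives=frozenset(positives), negatives=frozenset(negatives),
                    phenotype=phenotype, provenance="drug_snapshot")


# -------------------------------------------------------- normal-tissue filter

def restricted_normal_filter(
    report: ScoreReport,
    matrix: FeatureMatrix,
    feature: str = "normal_expr_max",
    pct: float = 20.0,
) -> list[str]:
    """Genes with restricted normal-tissue expression, in report order.

    Returns the report's genes whose ``feature`` value lies strictly
    below the pct-th percentile (linear interpolation) of that feature's
    non-missing distribution across all genes in the matrix. Genes with
    a missing value are never returned.
    """
    if not 0 < pct < 100 and pct != 100:
        raise ValidationError("pct must lie in (0, 100]")
    if feature not in matrix.values.columns:
        raise ValidationError(f"no such feature {feature!r}")
    col = matrix.values[feature]
    nonmiss = col.dropna()
    if nonmiss.empty:
        raise ValidationError(f"feature {feature!r} is entirely missing")
    threshold = float(np.percentile(nonmiss.to_numpy(dtype=float), pct))
    keep = col < threshold  # NaN compares False: missing never passes
    return [g for g in report.ranking() if bool(keep.get(g, False))]
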