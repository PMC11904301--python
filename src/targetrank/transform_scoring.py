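"""Per-feature rescaling, imputation, curving, weighting, and gene scores.

The pipeline order is fixed: rescale -> impute -> curve -> weight.
Imputation runs on rescaled values so fill constants are scale-free.
The final score of a gene is the weighted average of its curved feature
values, sum(w_i * curved_i) / sum(|w_i|), which keeps scores in [-1, 1]
and makes them invariant to rescaling all weights by a positive factor.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    FeatureMatrix,
    FeatureSpec,
    ParamVector,
    ScoreReport,
    ValidationError,
)

__all__ = ["rescale", "impute", "curve_value", "score_genes", "transform_matrix"]


def rescale(values: pd.Series, method: str) -> pd.Series:
    """Map a feature column into [0, 1]; missing entries stay missing.

    ``rank_percentile`` maps each non-missing value to (rank-1)/(n-1)
    with average ranks for ties; ``minmax`` to (x-min)/(max-min).
    Constant columns (including single-value columns) map to 0.5.
    """
    v = values.astype(float)
    mask = v.notna()
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("cannot rescale an all-missing column")
    out = pd.Series(np.nan, index=v.index, dtype=float)
    x = v[mask]
    if x.nunique() == 1:
        out[mask] = 0.5
        return out
    if method == "rank_percentile":
        out[mask] = (x.rank(method="average") - 1.0) / (n - 1.0)
    elif method == "minmax":
        lo, hi = x.min(), x.max()
        out[mask] = (x - lo) / (hi - lo)
    else:
        raise ValidationError(f"unknown rescale method {method!r}")
    return out


def impute(values: pd.Series, method: str) -> pd.Series:
    """Fill missing entries of a rescaled (already in [0,1]) column.

    ``zero`` encodes absence-of-evidence-contributes-nothing; ``neutral``
    fills the scale midpoint 0.5; ``min``/``median`` use that statistic
    of the non-missing entries.
    """
    out = values.astype(float).copy()
    mask = out.isna()
    if not mask.any():
        return out
    if method == "zero":
        fill = 0.0
    elif method == "neutral":
        fill = 0.5
    elif method == "min":
        fill = float(out[~mask].min())
    elif method == "median":
        fill = float(out[~mask].median())
    else:
        raise ValidationError(f"unknown impute method {method!r}")
    out[mask] = fill
    return out


def curve_value(v, c: float):
    """Monotone non-linear emphasis transform v ** exp(c) on [0, 1].

    c = 0 is the identity; c > 0 yields a convex transform that
    accentuates differences among high feature values, c < 0 a concave
    transform that accentuates differences among low values. Fixes 0
    and 1 and is strictly increasing for every finite c.
    """
    arr = np.asarray(v, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("curve_value input must lie in [0, 1]")
    if not np.isfinite(c):
        raise ValidationError("curve parameter must be finite")
    out = arr ** np.exp(c)
    return out if arr.ndim else float(out)


def transform_matrix(matrix: FeatureMatrix, specs: list[FeatureSpec] | None = None) -> pd.DataFrame:
    """Rescale and impute every enabled feature column (curve/weight not yet applied)."""
    specs = [s for s in (specs or matrix.catalog) if s.enabled]
    cols = {}
    for s in specs:
        cols[s.name] = impute(rescale(matrix.values[s.name], s.rescale_method), s.impute_method)
    return pd.DataFrame(cols, index=matrix.values.index)


def _rank_descending(scores: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """Order indices best-first: descending score, ties by ascending symbol."""
    return np.lexsort((genes, -scores))


def score_genes(
    matrix: FeatureMatrix,
    params: ParamVector | None = None,
) -> ScoreReport:
    """Score every gene by the weighted average of curved feature values.

    ``params`` overrides the catalog's weights/curves for the features it
    names and restricts scoring to those features; with ``params=None``
    the catalog defaults are used for all enabled features. Features
    with zero weight are excluded and provably do not affect the result.
    Ranks break score ties by ascending gene symbol so reports (and MAP)
    are reproducible.
    """
    if params is None:
        enabled = [s for s in matrix.catalog if s.enabled]
        weights = {s.name: float(s.weight) for s in enabled}
        curves = {s.name: float(s.curve) for s in enabled}
        names = [s.name for s in enabled]
    else:
        names = list(params.features)
        weights = {f: float(w) for f, w in zip(names, params.weights)}
        curves = {f: float(c) for f, c in zip(names, params.curves)}
        unknown = [f for f in names if f not in matrix.values.columns]
        if unknown:
            raise ValidationError(f"params name unknown features {unknown}")
    active = [f for f in names if weights[f] != 0.0]
    if not active:
        raise ValidationError("all feature weights are zero")

    specs = [matrix.spec(f) for f in names]
    scaled = transform_matrix(matrix, specs)

    sum_abs = sum(abs(weights[f]) for f in active)
    genes = matrix.values.index.to_numpy(dtype=object)
    table = matrix.values.loc[:, [s.name for s in specs]].copy()
    score = np.zeros(len(genes))
    for f in names:
        curved = curve_value(scaled[f].to_numpy(), curves[f])
        contrib = weights[f] * curved / sum_abs if f in active else np.zeros(len(genes))
        table[f + "__transformed"] = contrib
        score += contrib
    table["score"] = score

    order = _rank_descending(score, genes.astype(str))
    rank = np.empty(len(genes), dtype=int)
    rank[order] = np.arange(1, len(genes) + 1)
    table["rank"] = rank
    n = len(genes)
    table["percentile"] = 100.0 * (n - rank) / (n - 1) if n > 1 else 100.0
    table = table.sort_values("rank")
    return ScoreReport(table=table)
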