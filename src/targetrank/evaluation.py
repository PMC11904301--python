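"""Average precision and MAP over phenotype projects.

MAP here is the mean, over the known-positive targets, of the precision
at each positive's rank. Two negative-handling modes are provided:

* ``full`` — AP over the complete ranking; genes without a label count
  as non-relevant. Default when no known-negatives exist.
* ``labeled_only`` — the ranking is first restricted to the labeled
  genes (positives and negatives) and AP is computed on that
  sub-ranking. This is the variant that puts discontinued-drug targets
  "in consideration": a positive is penalized only by the negatives
  (and other positives) ranked above it. Default when negatives exist.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .datatypes import EvaluationResult, LabelSet, ValidationError

__all__ = ["average_precision", "map_over_projects"]


def _ap_positions(pos_positions: np.ndarray) -> tuple[float, np.ndarray]:
    """AP from 0-based positions of positives within a ranking (sorted)."""
    ranks = np.sort(pos_positions) + 1
    precisions = np.arange(1, len(ranks) + 1) / ranks
    return float(precisions.mean()), ranks


def average_precision(
    ranking: Sequence[str],
    labels: LabelSet,
    mode: str = "auto",
) -> EvaluationResult:
    """Score a best-first gene ranking against known positives/negatives.

    Parameters
    ----------
    ranking : ordered gene symbols, best first, no duplicates.
    labels : the known-positive / known-negative sets.
    mode : "full", "labeled_only", or "auto" (labeled_only when
        negatives exist, full otherwise).
    """
    genes = [str(g).upper() for g in ranking]
    if len(set(genes)) != len(genes):
        raise ValidationError("ranking contains duplicate genes")
    pos, neg = labels.positives, labels.negatives
    if not pos:
        raise ValidationError("label set has no positives")
    missing = pos - set(genes)
    if missing:
        raise ValidationError(f"positives absent from ranking: {sorted(missing)[:5]}")
    if mode == "auto":
        mode = "labeled_only" if neg else "full"
    if mode == "labeled_only":
        if not neg:
            raise ValidationError("labeled_only mode requires known-negatives")
        universe = [g for g in genes if g in pos or g in neg]
    elif mode == "full":
        universe = genes
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    positions = np.array([i for i, g in enumerate(universe) if g in pos])
    ap, ranks = _ap_positions(positions)
    gene_at = {i: g for i, g in enumerate(universe)}
    per_positive = [
        (gene_at[r - 1], int(r), float(k / r))
        for k, r in enumerate(ranks, start=1)
    ]
    return EvaluationResult(
        map=ap,
        per_positive=per_positive,
        mode=mode,
        n_positives=len(pos),
        n_negatives=len(neg),
    )


def map_over_projects(results: Iterable[EvaluationResult]) -> float:
    """Unweighted mean of per-project MAP scores."""
    values = [r.map for r in results]
    if not values:
        raise ValidationError("no evaluation results to average")
    return float(np.mean(values))
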