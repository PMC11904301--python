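"""Maximize MAP over feature weights and curves.

The optimization stack mirrors the intended usage order: sequential
forward selection (SFS) with per-feature Brent refinement first, to
find the subset of features that contributes to the ranking objective,
then a real-coded genetic algorithm with periodic Nelder-Mead
refinement of the best individual to polish the weight/curve vector.

Two strategies are supported: ``multi_cancer`` evaluates the mean MAP
across all supplied phenotype projects at once; ``phenotype_specific``
optimizes on a single project. All stochasticity flows from one integer
seed; identical seeds give bit-identical results.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize as sciopt

from .datatypes import (
    DEFAULT_CURVE_BOUNDS,
    DEFAULT_WEIGHT_BOUNDS,
    FeatureMatrix,
    LabelSet,
    OptimizationResult,
    ParamVector,
    ValidationError,
)
from .transform_scoring import transform_matrix

logger = logging.getLogger("targetrank")

__all__ = [
    "Project",
    "MapObjective",
    "objective",
    "brent_maximize",
    "nelder_mead_maximize",
    "sfs_optimize",
    "ga_optimize",
    "optimize_pipeline",
]


@dataclass
class Project:
    """One phenotype's feature matrix with its label set."""

    matrix: FeatureMatrix
    labels: LabelSet


class MapObjective:
    """Mean MAP across projects as a function of (features, weights, curves).

    Rescaling and imputation do not depend on weights or curves, so the
    transformed matrix is computed once per project and reused; each
    evaluation then only curves, weighted-averages, ranks, and computes
    AP. Evaluations are memoized by the exact parameter bytes — the
    cache changes speed, never results.
    """

    def __init__(self, projects: Sequence[Project], mode: str = "auto"):
        if not projects:
            raise ValidationError("objective needs at least one project")
        self._prepared = []
        for proj in projects:
            R = transform_matrix(proj.matrix)
            genes = np.array([str(g) for g in R.index], dtype=object)
            tie_rank = np.argsort(np.argsort(genes))  # ascending-symbol tiebreak
            pos = np.isin(genes, sorted(proj.labels.positives))
            if not pos.any():
                raise ValidationError(
                    f"no positives present in project {proj.labels.phenotype!r}")
            neg = np.isin(genes, sorted(proj.labels.negatives))
            m = mode
            if m == "auto":
                m = "labeled_only" if neg.any() else "full"
            if m == "labeled_only" and not neg.any():
                raise ValidationError("labeled_only mode requires known-negatives")
            self._prepared.append(
                (R, {c: i for i, c in enumerate(R.columns)},
                 np.ascontiguousarray(R.to_numpy(dtype=float)),
                 tie_rank, pos, neg, m))
        self.feature_names = list(self._prepared[0][0].columns)
        self.n_evaluations = 0
        self._cache: dict[bytes, float] = {}

    def _project_ap(self, prep, cols: np.ndarray, weights: np.ndarray,
                    curves: np.ndarray) -> float:
        _, _, X, tie_rank, pos, neg, m = prep
        curved = X[:, cols] ** np.exp(curves)[None, :]
        scores = curved @ weights / np.abs(weights).sum()
        order = np.lexsort((tie_rank, -scores))
        if m == "labeled_only":
            order = order[pos[order] | neg[order]]
        hits = pos[order]
        ranks = np.flatnonzero(hits) + 1
        return float((np.arange(1, len(ranks) + 1) / ranks).mean())

    def __call__(self, params: ParamVector) -> float:
        active = [(f, w, c) for f, w, c in
                  zip(params.features, params.weights, params.curves) if w != 0.0]
        if not active:
            raise ValidationError("all feature weights are zero")
        key = (tuple(f for f, _, _ in active),
               np.array([(w, c) for _, w, c in active]).tobytes())
        k = repr(key[0]).encode() + key[1]
        if k in self._cache:
            return self._cache[k]
        weights = np.array([w for _, w, _ in active])
        curves = np.array([c for _, _, c in active])
        aps = []
        for prep in self._prepared:
            colmap = prep[1]
            cols = np.array([colmap[f] for f, _, _ in active])
            aps.append(self._project_ap(prep, cols, weights, curves))
        val = float(np.mean(aps))
        self.n_evaluations += 1
        self._cache[k] = val
        return val


def objective(params: ParamVector, projects: Sequence[Project],
              mode: str = "auto") -> float:
    """Mean MAP across projects for one parameter vector (pure function)."""
    return MapObjective(projects, mode=mode)(params)


# ---------------------------------------------------------------- local search

def brent_maximize(
    f: Callable[[float], float],
    bounds: tuple[float, float],
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Bounded scalar maximization (Brent-style parabolic/golden search)."""
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValidationError("bounds must be a finite nonempty interval")

    def neg(x: float) -> float:
        v = f(float(x))
        if not np.isfinite(v):
            raise ValidationError(f"objective returned non-finite value at {x}")
        return -v

    res = sciopt.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                 options={"xatol": tol, "maxiter": max_iter})
    x = float(np.clip(res.x, lo, hi))
    return x, -float(res.fun)


def nelder_mead_maximize(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Derivative-free simplex maximization (reflection/expansion/contraction/shrink)."""
    x0 = np.asarray(x0, dtype=float)
    scipy_bounds = None
    if bounds is not None:
        lo, hi = bounds
        x0 = np.clip(x0, lo, hi)
        scipy_bounds = sciopt.Bounds(lo, hi)

    def neg(x: np.ndarray) -> float:
        v = f(x)
        if not np.isfinite(v):
            raise ValidationError("objective returned non-finite value")
        return -v

    res = sciopt.minimize(neg, x0, method="Nelder-Mead", bounds=scipy_bounds,
                          options={"xatol": tol, "fatol": tol,
                                   "maxiter": max_iter, "adaptive": True})
    x = np.asarray(res.x, dtype=float)
    if bounds is not None:
        x = np.clip(x, bounds[0], bounds[1])
    best = -float(res.fun)
    f0 = f(x0)
    if f0 >= best:  # never return worse than the start
        return x0, float(f0)
    return x, best


def _rel_improvement(new: float, current: float) -> float:
    if current == 0.0:
        return np.inf if new > 0 else 0.0
    return (new - current) / abs(current)


# ------------------------------------------------------------------------ SFS

def _default_params(matrix: FeatureMatrix, features: Sequence[str],
                    weight_bounds, curve_bounds) -> ParamVector:
    specs = {s.name: s for s in matrix.catalog}
    return ParamVector(
        list(features),
        np.array([specs[f].weight for f in features], dtype=float),
        np.array([specs[f].curve for f in features], dtype=float),
        weight_bounds, curve_bounds,
    )


def sfs_optimize(
    projects: Sequence[Project],
    improve_threshold: float = 1e-4,
    brent_refine: bool = True,
    brent_tol: float = 1e-4,
    weight_bounds: tuple[float, float] = DEFAULT_WEIGHT_BOUNDS,
    curve_bounds: tuple[float, float] = DEFAULT_CURVE_BOUNDS,
    mode: str = "auto",
) -> OptimizationResult:
    """Greedy sequential forward selection with per-feature Brent refinement.

    Starting from the default-parameter objective over the full enabled
    catalog as the baseline, features are added greedily: at each round
    every unselected candidate is scored together with the current
    selection (default parameters for the newcomer), the best candidate
    is kept only if it improves the current objective by at least
    ``improve_threshold`` (a relative fraction), and after inclusion its
    weight and then its curve are refined one at a time by Brent's
    method. Ties between candidates break by catalog order; the whole
    procedure is deterministic. If no candidate ever clears the
    threshold the default-parameter result is returned unchanged.
    """
    if improve_threshold < 0:
        raise ValidationError("improve_threshold must be nonnegative")
    obj = MapObjective(projects, mode=mode)
    matrix = projects[0].matrix
    all_features = [s.name for s in matrix.catalog if s.enabled]
    baseline_params = _default_params(matrix, all_features, weight_bounds, curve_bounds)
    baseline = obj(baseline_params)

    specs = {s.name: s for s in matrix.catalog}
    selected: list[str] = []
    values: dict[str, tuple[float, float]] = {}  # feature -> (weight, curve)
    current = baseline
    trace = [baseline]
    log = [f"sfs: baseline MAP {baseline:.6f} over {len(all_features)} features"]

    def make_params(feats: Sequence[str], over: dict | None = None) -> ParamVector:
        over = over or {}
        w = [over.get(f, values.get(f, (specs[f].weight, specs[f].curve)))[0]
             for f in feats]
        c = [over.get(f, values.get(f, (specs[f].weight, specs[f].curve)))[1]
             for f in feats]
        return ParamVector(list(feats), np.array(w), np.array(c),
                           weight_bounds, curve_bounds)

    while True:
        candidates = [f for f in all_features if f not in selected]
        if not candidates:
            break
        best_f, best_val = None, -np.inf
        for f in candidates:  # catalog order; strict > keeps first on ties
            val = obj(make_params(selected + [f]))
            if val > best_val:
                best_f, best_val = f, val
        if _rel_improvement(best_val, current) < improve_threshold:
            log.append(f"sfs: stop, best candidate {best_f} at {best_val:.6f} "
                       f"does not clear threshold {improve_threshold}")
            break
        selected.append(best_f)
        values[best_f] = (float(specs[best_f].weight), float(specs[best_f].curve))
        current = best_val
        log.append(f"sfs: include {best_f}, MAP {current:.6f}")
        if brent_refine:
            for slot in (0, 1):  # weight first, then curve
                bounds = weight_bounds if slot == 0 else curve_bounds

                def f1(x: float, _f=best_f, _slot=slot) -> float:
                    w, c = values[_f]
                    trial = (x, c) if _slot == 0 else (w, x)
                    if _slot == 0 and x == 0.0:
                        # zero weight excludes the feature; a lone feature
                        # cannot be excluded, so score it strictly worst
                        return -1.0 if len(selected) == 1 else obj(
                            make_params([g for g in selected if g != _f]))
                    return obj(make_params(selected, {_f: trial}))

                x, val = brent_maximize(f1, bounds, tol=brent_tol)
                if np.isfinite(val) and val > current:
                    w, c = values[best_f]
                    values[best_f] = (x, c) if slot == 0 else (w, x)
                    current = val
            log.append(f"sfs: refined {best_f} -> {values[best_f]}, MAP {current:.6f}")
        trace.append(current)

    if selected:
        params = make_params(selected)
        final = current
    else:
        params = baseline_params
        final = baseline
    return OptimizationResult(params=params, selected=list(selected), trace=trace,
                              initial_map=baseline, final_map=final,
                              method_log=log)


# ------------------------------------------------------------------------- GA

def ga_optimize(
    projects: Sequence[Project],
    init: ParamVector,
    population: int = 40,
    generations: int = 60,
    mutation_sd: float | None = None,
    mutation_rate: float = 0.15,
    crossover_rate: float = 0.9,
    tournament: int = 3,
    elitism: int = 1,
    nm_refine: bool = True,
    nm_every: int = 10,
    nm_improve_threshold: float = 1e-3,
    seed: int = 0,
    mode: str = "auto",
) -> OptimizationResult:
    """Real-coded genetic algorithm over the (weights, curves) vector.

    Tournament selection, uniform crossover, per-gene Gaussian mutation
    clipped to bounds, and single-individual elitism. Every ``nm_every``
    generations the best individual is refined by Nelder-Mead and the
    refined vector replaces it only if the relative improvement is at
    least ``nm_improve_threshold``. The best-so-far trace is
    non-decreasing by construction and identical seeds reproduce the
    run bit for bit.
    """
    if population < 2:
        raise ValidationError("population must be at least 2")
    obj = MapObjective(projects, mode=mode)
    lo, hi = init.bounds_arrays()
    d = len(lo)
    if mutation_sd is None:
        sd = 0.1 * (hi - lo)
    else:
        sd = np.full(d, float(mutation_sd))
    rng = np.random.default_rng(seed)

    def fitness(x: np.ndarray) -> float:
        pv = init.with_array(x)
        if not np.any(pv.weights != 0.0):
            return -1.0  # degenerate all-zero-weight vector scores worst
        return obj(pv)

    x0 = init.to_array()
    pop = np.empty((population, d))
    pop[0] = x0
    half = population // 2
    for i in range(1, half):  # local cloud around the seed vector
        pop[i] = np.clip(x0 + rng.normal(0.0, sd), lo, hi)
    for i in range(half, population):  # global exploration
        pop[i] = rng.uniform(lo, hi)
    fit = np.array([fitness(x) for x in pop])

    best_idx = int(np.argmax(fit))
    best_x, best_f = pop[best_idx].copy(), float(fit[best_idx])
    initial = float(fit[0]) if np.isfinite(fit[0]) else best_f
    trace = [best_f]
    log = [f"ga: init best MAP {best_f:.6f} (seed {seed}, pop {population})"]

    for gen in range(1, generations + 1):
        order = np.argsort(-fit)
        new = [pop[order[i]].copy() for i in range(elitism)]
        while len(new) < population:
            idx = rng.integers(0, population, size=(2, tournament))
            p1 = pop[idx[0][np.argmax(fit[idx[0]])]]
            p2 = pop[idx[1][np.argmax(fit[idx[1]])]]
            if rng.random() < crossover_rate:
                mask = rng.random(d) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mut = rng.random(d) < mutation_rate
            child = np.where(mut, child + rng.normal(0.0, sd), child)
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fit = np.array([fitness(x) for x in pop])
        gi = int(np.argmax(fit))
        if fit[gi] > best_f:
            best_x, best_f = pop[gi].copy(), float(fit[gi])
        if nm_refine and gen % nm_every == 0:
            xr, fr = nelder_mead_maximize(fitness, best_x, bounds=(lo, hi),
                                          max_iter=50 * d)
            if _rel_improvement(fr, best_f) >= nm_improve_threshold:
                log.append(f"ga: gen {gen} NM refinement {best_f:.6f} -> {fr:.6f}")
                best_x, best_f = xr.copy(), float(fr)
                worst = int(np.argmin(fit))
                pop[worst], fit[worst] = best_x, best_f
        trace.append(best_f)
    log.append(f"ga: final MAP {best_f:.6f} after {generations} generations, "
               f"{obj.n_evaluations} distinct evaluations")
    return OptimizationResult(params=init.with_array(best_x), selected=list(init.features),
                              trace=trace, initial_map=min(initial, best_f),
                              final_map=best_f, seed=seed, method_log=log)


# -------------------------------------------------------------------- pipeline

def optimize_pipeline(
    projects: Sequence[Project],
    strategy: str = "multi_cancer",
    seed: int = 0,
    sfs_threshold: float = 1e-4,
    nm_threshold: float = 1e-3,
    population: int = 40,
    generations: int = 60,
    weight_bounds: tuple[float, float] = DEFAULT_WEIGHT_BOUNDS,
    curve_bounds: tuple[float, float] = DEFAULT_CURVE_BOUNDS,
    mode: str = "auto",
    phenotype: str | None = None,
) -> OptimizationResult:
    """Full optimization stack: SFS + Brent, then GA + Nelder-Mead.

    ``multi_cancer`` maximizes the mean MAP across all supplied
    projects; ``phenotype_specific`` restricts to one project (by
    ``phenotype``, defaulting to the first). The GA is seeded with the
    SFS result so the final MAP can only improve on it.
    """
    if strategy == "phenotype_specific":
        if phenotype is not None:
            sel = [p for p in projects if p.labels.phenotype == phenotype]
            if not sel:
                raise ValidationError(f"no project with phenotype {phenotype!r}")
            projects = sel[:1]
        else:
            projects = list(projects)[:1]
    elif strategy != "multi_cancer":
        raise ValidationError(f"unknown strategy {strategy!r}")

    sfs = sfs_optimize(projects, improve_threshold=sfs_threshold,
                       weight_bounds=weight_bounds, curve_bounds=curve_bounds,
                       mode=mode)
    ga = ga_optimize(projects, sfs.params, population=population,
                     generations=generations, nm_improve_threshold=nm_threshold,
                     seed=seed, mode=mode)
    final = max(sfs.final_map, ga.final_map)
    params = ga.params if ga.final_map >= sfs.final_map else sfs.params
    return OptimizationResult(
        params=params,
        selected=sfs.selected or list(sfs.params.features),
        trace=sfs.trace + ga.trace,
        initial_map=sfs.initial_map,
        final_map=final,
        strategy=strategy,
        seed=seed,
        method_log=sfs.method_log + ga.method_log,
    )
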