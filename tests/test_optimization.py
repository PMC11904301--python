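import itertools

import numpy as np
import pandas as pd
import pytest

import targetrank as tr
from targetrank.datatypes import FeatureSpec
from targetrank.optimization import MapObjective, _rel_improvement


def toy_project(signal_strengths, n_genes=30, n_pos=4, seed=0, neg=0):
    """Toy project whose feature j carries label signal signal_strengths[j]."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    pos = set(rng.choice(genes, size=n_pos, replace=False))
    rest = [g for g in genes if g not in pos]
    negs = set(rng.choice(rest, size=neg, replace=False)) if neg else set()
    is_pos = np.array([g in pos for g in genes], dtype=float)
    cols, catalog = {}, []
    for j, alpha in enumerate(signal_strengths):
        cols[f"f{j}"] = alpha * is_pos + rng.normal(0, 1, n_genes)
        catalog.append(FeatureSpec(f"f{j}", "annotation", f"snapshot:x:f{j}"))
    matrix = tr.FeatureMatrix(values=pd.DataFrame(cols, index=genes),
                              catalog=catalog)
    labels = tr.LabelSet(positives=frozenset(pos), negatives=frozenset(negs),
                         phenotype="TOY")
    return tr.Project(matrix=matrix, labels=labels)


def default_params(project):
    feats = [s.name for s in project.matrix.catalog if s.enabled]
    return tr.ParamVector(feats, np.ones(len(feats)), np.zeros(len(feats)))


class TestObjective:
    def test_perfect_separation_scores_one(self):
        proj = toy_project([100.0], seed=1)
        assert tr.objective(default_params(proj), [proj]) == 1.0

    def test_multi_project_mean(self):
        p1 = toy_project([100.0], seed=1)
        p2 = toy_project([0.0], seed=2)
        v1 = tr.objective(default_params(p1), [p1])
        v2 = tr.objective(default_params(p2), [p2])
        both = tr.objective(default_params(p1), [p1, p2])
        assert both == pytest.approx((v1 + v2) / 2)

    def test_pure_function(self):
        proj = toy_project([3.0, 0.5], seed=3)
        params = default_params(proj)
        vals = {tr.objective(params, [proj]) for _ in range(5)}
        assert len(vals) == 1

    def test_zero_weights_rejected(self):
        proj = toy_project([1.0], seed=1)
        params = tr.ParamVector(["f0"], np.array([0.0]), np.array([0.0]))
        with pytest.raises(tr.ValidationError):
            tr.objective(params, [proj])


class TestBrent:
    def test_concave_quadratic(self):
        x, fx = tr.brent_maximize(lambda w: -((w - 2.0) ** 2), (0.0, 5.0))
        assert abs(x - 2.0) < 1e-4

    def test_increasing_function_hits_upper_bound(self):
        x, _ = tr.brent_maximize(lambda w: w, (0.0, 1.0), tol=1e-5)
        assert x > 1.0 - 1e-3

    def test_matches_grid_oracle_on_random_quadratics(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.uniform(0.5, 4.0)
            b = rng.uniform(-4.0, 4.0)
            f = lambda w: -a * (w - b) ** 2
            x, _ = tr.brent_maximize(f, (-5.0, 5.0))
            grid = np.linspace(-5, 5, 200001)
            x_grid = grid[np.argmax(f(grid))]
            assert abs(x - x_grid) < 1e-3

    def test_rejects_bad_inputs(self):
        with pytest.raises(tr.ValidationError):
            tr.brent_maximize(lambda w: w, (0.0, np.inf))
        with pytest.raises(tr.ValidationError):
            tr.brent_maximize(lambda w: np.nan, (0.0, 1.0))


class TestNelderMead:
    def test_recovers_origin(self):
        x, fx = tr.nelder_mead_maximize(lambda v: -(v[0] ** 2 + v[1] ** 2),
                                        np.array([1.0, 1.0]))
        assert np.all(np.abs(x) < 1e-3)

    def test_constant_function_returns_start(self):
        x0 = np.array([0.3, -0.2])
        x, fx = tr.nelder_mead_maximize(lambda v: 7.0, x0)
        assert np.array_equal(x, x0) and fx == 7.0

    def test_matches_closed_form_on_random_quadratics(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            center = rng.uniform(-1, 1, size=3)
            scale = rng.uniform(0.5, 3.0, size=3)
            f = lambda v: -np.sum(scale * (v - center) ** 2)
            x, _ = tr.nelder_mead_maximize(f, np.zeros(3), tol=1e-9,
                                           max_iter=2000)
            assert np.all(np.abs(x - center) < 1e-3)

    def test_respects_bounds(self):
        lo, hi = np.array([-1.0, -1.0]), np.array([0.5, 0.5])
        x, _ = tr.nelder_mead_maximize(lambda v: v.sum(), np.zeros(2),
                                       bounds=(lo, hi))
        assert np.all(x >= lo) and np.all(x <= hi)


class TestSFS:
    def test_threshold_one_returns_default_result(self):
        # moderate signals: no single feature can double the baseline MAP
        proj = toy_project([1.0, 0.8, 0.6], seed=6)
        res = tr.sfs_optimize([proj], improve_threshold=1.0)
        assert res.selected == []
        assert res.final_map == res.initial_map
        assert sorted(res.params.features) == ["f0", "f1", "f2"]

    def test_single_separating_feature_is_selected_alone(self):
        # only f1 carries signal; exhaustive search agrees
        proj = toy_project([0.0, 100.0, 0.0], seed=8)
        res = tr.sfs_optimize([proj])
        assert res.selected == ["f1"]
        assert res.final_map == 1.0
        obj = MapObjective([proj])
        feats = ["f0", "f1", "f2"]
        best = max(
            obj(tr.ParamVector(list(sub), np.ones(len(sub)), np.zeros(len(sub))))
            for r in range(1, 4) for sub in itertools.combinations(feats, r))
        assert res.final_map == pytest.approx(best)

    def test_trace_non_decreasing_and_bounded_by_oracle(self):
        for seed in range(5):
            proj = toy_project([2.0, 1.0, 0.5, 0.0], seed=seed)
            res = tr.sfs_optimize([proj], brent_refine=False,
                                  improve_threshold=0.0)
            assert all(b >= a - 1e-12 for a, b in zip(res.trace, res.trace[1:]))
            obj = MapObjective([proj])
            feats = [s.name for s in proj.matrix.catalog]
            oracle = max(
                obj(tr.ParamVector(list(sub), np.ones(len(sub)),
                                   np.zeros(len(sub))))
                for r in range(1, 5) for sub in itertools.combinations(feats, r))
            assert res.final_map <= oracle + 1e-12

    def test_negative_threshold_rejected(self):
        proj = toy_project([1.0], seed=1)
        with pytest.raises(tr.ValidationError):
            tr.sfs_optimize([proj], improve_threshold=-0.1)


class TestGA:
    @pytest.fixture()
    def project(self):
        return toy_project([2.0, 0.5], n_genes=40, seed=9)

    def ga(self, project, seed=3):
        init = default_params(project)
        return tr.ga_optimize([project], init, population=12, generations=8,
                              nm_every=4, seed=seed)

    def test_trace_non_decreasing(self, project):
        res = self.ga(project)
        assert all(b >= a - 1e-15 for a, b in zip(res.trace, res.trace[1:]))

    def test_same_seed_bit_identical(self, project):
        r1, r2 = self.ga(project, seed=5), self.ga(project, seed=5)
        assert np.array_equal(r1.params.weights, r2.params.weights)
        assert np.array_equal(r1.params.curves, r2.params.curves)
        assert r1.trace == r2.trace
        assert r1.final_map == r2.final_map

    def test_bounds_respected(self, project):
        res = self.ga(project)
        lo_w, hi_w = res.params.weight_bounds
        lo_c, hi_c = res.params.curve_bounds
        assert np.all((res.params.weights >= lo_w) & (res.params.weights <= hi_w))
        assert np.all((res.params.curves >= lo_c) & (res.params.curves <= hi_c))

    def test_final_at_least_initial(self, project):
        res = self.ga(project)
        assert res.final_map >= res.initial_map

    def test_population_size_validated(self, project):
        with pytest.raises(tr.ValidationError):
            tr.ga_optimize([project], default_params(project), population=1)


class TestPipeline:
    def test_stage_ordering_improves_map(self):
        proj1 = toy_project([3.0, 1.0, 0.0], n_genes=50, n_pos=6, seed=10)
        proj2 = toy_project([2.5, 0.5, 0.2], n_genes=50, n_pos=6, seed=11)
        sfs = tr.sfs_optimize([proj1, proj2])
        full = tr.optimize_pipeline([proj1, proj2], seed=1, population=12,
                                    generations=8)
        assert full.final_map >= sfs.final_map >= sfs.initial_map
        assert full.initial_map == sfs.initial_map

    def test_single_project_strategies_coincide(self):
        proj = toy_project([2.0, 0.5], n_genes=40, seed=12)
        a = tr.optimize_pipeline([proj], strategy="multi_cancer", seed=2,
                                 population=10, generations=5)
        b = tr.optimize_pipeline([proj], strategy="phenotype_specific", seed=2,
                                 population=10, generations=5)
        assert a.final_map == b.final_map
        assert np.array_equal(a.params.weights, b.params.weights)

    def test_cross_phenotype_application_runs(self):
        train = toy_project([3.0, 0.0], n_genes=40, seed=13)
        other = toy_project([0.0, 3.0], n_genes=40, seed=14)
        res = tr.optimize_pipeline([train], strategy="phenotype_specific",
                                   seed=3, population=10, generations=5)
        v_other = tr.objective(res.params, [other])
        assert 0.0 < v_other <= 1.0

    def test_unknown_strategy_rejected(self):
        proj = toy_project([1.0], seed=1)
        with pytest.raises(tr.ValidationError):
            tr.optimize_pipeline([proj], strategy="bogus")

    def test_rel_improvement_semantics(self):
        assert _rel_improvement(1.1, 1.0) == pytest.approx(0.1)
        assert _rel_improvement(0.5, 0.0) == np.inf
        assert _rel_improvement(0.0, 0.0) == 0.0
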