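import warnings

import numpy as np
import pandas as pd
import pytest

from gsmdep.depletion import (
    ContrastStatistics,
    DepletionCurve,
    ExpressionDesign,
    GeneSet,
    abs_area,
    auc_delta,
    average_curve,
    build_series,
    make_grid,
    prepare_gene_sets,
    rank_genes,
    read_gmt,
    step_integral,
    write_gmt,
)


class TestGeneSets:
    def test_gmt_roundtrip(self, tmp_path):
        sets = [GeneSet("S1", frozenset({"a", "b", "c"}), "first"),
                GeneSet("S2", frozenset({"d", "e"}), "second")]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_size_filter_boundaries(self, default_network):
        genes = sorted(default_network.genes)
        too_small = GeneSet("small", frozenset(genes[:2]))
        at_floor = GeneSet("floor", frozenset(genes[:3]))
        wide = GeneSet("wide", frozenset(genes + [f"z{i}" for i in range(60)]))
        prepared = prepare_gene_sets([too_small, at_floor, wide], default_network,
                                     max_size=50)
        names = {s.name for s in prepared}
        assert names == {"floor", "wide"}
        # members restricted to network genes
        assert all(s.members <= default_network.genes for s in prepared)

    def test_filter_matches_brute_force(self, default_network):
        rng = np.random.default_rng(1)
        genes = sorted(default_network.genes)
        decoys = [f"x{i}" for i in range(100)]
        sets = []
        for i in range(10):
            size = int(rng.integers(1, 15))
            pool = genes + decoys
            members = frozenset(rng.choice(pool, size, replace=False))
            sets.append(GeneSet(f"S{i}", members))
        survivors = {s.name for s in prepare_gene_sets(sets, default_network)}
        expected = {
            s.name for s in sets
            if 3 <= len(s.members & default_network.genes) <= 50
        }
        assert survivors == expected

    def test_enrichment_prefilter(self, default_network):
        genes = sorted(default_network.genes)
        universe = genes + [f"x{i}" for i in range(970)]
        enriched = GeneSet("enr", frozenset(genes[:8]))  # all in network
        diluted = GeneSet("dil", frozenset(genes[:3] + [f"x{i}" for i in range(40)]))
        kept = prepare_gene_sets([enriched, diluted], default_network,
                                 universe=universe)
        assert {s.name for s in kept} == {"enr"}


class TestRanking:
    def test_ascending_order(self):
        assert rank_genes({"gA": 5, "gB": 1, "gC": 9}) == ["gB", "gA", "gC"]

    def test_ties_break_lexicographically(self):
        assert rank_genes({"b": 1.0, "a": 1.0, "c": 1.0}) == ["a", "b", "c"]

    def test_matches_reference_sort(self):
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.random(50), index=[f"g{i:02d}" for i in range(50)])
        expected = list(vals.sort_values(kind="stable").index)  # unique values
        assert rank_genes(vals) == expected


class TestSeries:
    def test_step_k_gives_two_submodels(self, small_network):
        ranking = sorted(small_network.genes)
        series = build_series(small_network, ranking, step=small_network.k)
        assert [s.i for s in series] == [0, small_network.k]

    def test_fitness_star_is_definitional(self, small_network):
        ranking = sorted(small_network.genes)
        k = small_network.k
        series = build_series(small_network, ranking, step=1)
        for sub in series:
            assert sub.fitness_star == pytest.approx((1 - sub.i / k) * sub.fitness)

    def test_incremental_walk_equals_fresh_extraction(self, small_network):
        from gsmdep.network import extract_submodel

        ranking = sorted(small_network.genes)
        series = build_series(small_network, ranking, step=1)
        for sub in series:
            fresh = extract_submodel(small_network, sub.removed_genes)
            assert set(sub.active_reactions) == set(fresh.active_reactions)
            assert sub.fitness == fresh.fitness

    def test_bad_ranking_rejected(self, small_network):
        with pytest.raises(ValueError):
            build_series(small_network, sorted(small_network.genes)[:-1])


class TestCurves:
    def test_first_knot_is_one(self, toy_chain):
        series = build_series(toy_chain, ["g1", "g2", "g3"], step=1)
        curve = DepletionCurve.from_series(series, GeneSet("g", frozenset({"g2", "g3"})))
        assert curve.knots[1][0] == 1.0
        assert curve.values[-1] == 1.0  # grid point x = 1

    def test_propagation_drop(self, toy_chain):
        """Removing g2 (not in the set) prunes R3, so the set {g1, g3}
        loses g3 at that knot: a 1/2 drop caused by an outside gene."""
        series = build_series(toy_chain, ["g2", "g1", "g3"], step=1)
        curve = DepletionCurve.from_series(series, GeneSet("g", frozenset({"g1", "g3"})))
        _, ys = curve.knots
        assert ys[0] == 1.0
        assert ys[1] == 0.5  # g3 pruned away when g2 is removed

    def test_curve_non_increasing_along_series(self, null_series):
        _, _, series_map = null_series
        rng = np.random.default_rng(4)
        net_genes = sorted(next(iter(series_map.values()))[0].parent.genes)
        for _ in range(5):
            gs = GeneSet("r", frozenset(rng.choice(net_genes, 6, replace=False)))
            for series in series_map.values():
                _, ys = DepletionCurve.from_series(series, gs).knots
                assert np.all(np.diff(ys) <= 1e-12)

    def test_average_identical_is_identity(self):
        grid = make_grid(101)
        c = DepletionCurve("a", grid, np.linspace(1, 0, 101))
        avg = average_curve([c, c, c])
        assert np.allclose(avg.values, c.values)

    def test_average_of_constants(self):
        grid = make_grid(101)
        ones = DepletionCurve("u", grid, np.ones(101))
        zeros = DepletionCurve("v", grid, np.zeros(101))
        assert np.allclose(average_curve([ones, zeros]).values, 0.5)

    def test_average_matches_dense_grid_mean(self):
        rng = np.random.default_rng(6)
        grid = make_grid(1001)
        curves = []
        for _ in range(4):
            kx = np.sort(rng.random(8))[::-1]
            kx = np.concatenate([[1.0], kx, [0.0]])
            ky = np.sort(rng.random(10))[::-1]
            ky = np.concatenate([[1.0], ky])
            vals = DepletionCurve.evaluate_knots(kx, ky, grid)
            curves.append(DepletionCurve("c", grid, vals, knots=(kx, ky)))
        avg = average_curve(curves)
        fine = make_grid(10001)
        fine_mean = np.mean(
            [DepletionCurve.evaluate_knots(*c.knots, fine) for c in curves], axis=0
        )
        assert np.allclose(avg.values, fine_mean[::10])


def _random_grid_step_curve(rng, grid):
    """A random non-increasing step curve whose jumps sit on the grid."""
    n_jumps = int(rng.integers(1, 12))
    jump_at = np.sort(rng.choice(len(grid) - 2, n_jumps, replace=False)) + 1
    levels = np.sort(rng.random(n_jumps + 1))  # ascending with x
    values = np.full(len(grid), levels[0])
    for lvl, idx in zip(levels[1:], jump_at):
        values[idx:] = lvl
    return DepletionCurve("r", grid, values)


class TestAreas:
    def test_identical_curves_zero(self):
        grid = make_grid()
        c = DepletionCurve("c", grid, np.linspace(1, 0, len(grid)))
        assert abs_area(c, c) == 0.0
        assert auc_delta(c, c)[2] == 0.0

    def test_constant_one_vs_zero(self):
        grid = make_grid()
        u = DepletionCurve("u", grid, np.ones(len(grid)))
        v = DepletionCurve("v", grid, np.zeros(len(grid)))
        assert abs_area(u, v) == pytest.approx(1.0)
        auc_u, auc_v, delta = auc_delta(u, v)
        assert (auc_u, auc_v, delta) == pytest.approx((1.0, 0.0, 1.0))

    def test_refinement_oracle(self):
        """Integrals on the working grid match a 10x-refined evaluation
        of the same step function to 1e-6."""
        rng = np.random.default_rng(7)
        grid = make_grid(1001)
        fine = make_grid(10001)
        mids = 0.5 * (fine[1:] + fine[:-1])  # never coincide with a knot
        dx = np.diff(fine)
        for _ in range(20):
            u = _random_grid_step_curve(rng, grid)
            v = _random_grid_step_curve(rng, grid)
            # midpoint quadrature of the materialised step functions
            fu = DepletionCurve.evaluate_knots(grid[::-1], u.values[::-1], mids)
            fv = DepletionCurve.evaluate_knots(grid[::-1], v.values[::-1], mids)
            a_fine = float(np.sum(np.abs(fu - fv) * dx))
            d_fine = float(np.sum((fu - fv) * dx))
            assert abs(abs_area(u, v) - a_fine) < 1e-6
            assert abs(auc_delta(u, v)[2] - d_fine) < 1e-6

    def test_delta_bounded_by_abs_area(self):
        rng = np.random.default_rng(8)
        grid = make_grid(201)
        for _ in range(1000):
            u = DepletionCurve("u", grid, rng.random(len(grid)))
            v = DepletionCurve("v", grid, rng.random(len(grid)))
            a = abs_area(u, v)
            assert abs(auc_delta(u, v)[2]) <= a + 1e-12
            assert a <= 1.0 + 1e-12

    def test_abs_area_is_a_pseudometric(self):
        rng = np.random.default_rng(9)
        grid = make_grid(101)
        for _ in range(200):
            u, v, w = (DepletionCurve("c", grid, rng.random(len(grid)))
                       for _ in range(3))
            assert abs_area(u, v) == pytest.approx(abs_area(v, u))
            assert abs_area(u, w) <= abs_area(u, v) + abs_area(v, w) + 1e-12

    def test_grid_resolution_stability(self, null_series, default_network):
        """Ā moves by < 1e-3 between 1001- and 10001-point grids on real
        series-derived curves."""
        _, design, series_map = null_series
        genes = sorted(default_network.genes)
        gs = GeneSet("s", frozenset(genes[:6]))
        samples = list(series_map)[:2]
        areas = {}
        for n_points in (1001, 10001):
            grid = make_grid(n_points)
            cu = DepletionCurve.from_series(series_map[samples[0]], gs, grid)
            cv = DepletionCurve.from_series(series_map[samples[1]], gs, grid)
            areas[n_points] = abs_area(cu, cv)
        assert abs(areas[1001] - areas[10001]) < 1e-3

    def test_contrast_statistics_flip_negates_delta(self):
        grid = make_grid(101)
        u = DepletionCurve("u", grid, np.linspace(1, 0.2, 101))
        v = DepletionCurve("v", grid, np.linspace(1, 0.0, 101))
        uv = ContrastStatistics.from_curves(u, v, ("U", "V"))
        vu = ContrastStatistics.from_curves(v, u, ("V", "U"))
        assert uv.delta == pytest.approx(-vu.delta)
        assert uv.abs_area == pytest.approx(vu.abs_area)
        assert uv.abs_area >= abs(uv.delta) - 1e-12


def test_missing_network_genes_imputed_with_warning(toy_chain):
    values = pd.DataFrame({"s1": [5.0, 2.0], "s2": [1.0, 3.0]},
                          index=["g1", "g2"])  # g3 missing
    design = ExpressionDesign(values=values, condition_of={"s1": "U", "s2": "V"})
    with pytest.warns(UserWarning, match="imputed at 0"):
        aligned = design.align_to_network(toy_chain)
    assert aligned.values.loc["g3"].eq(0).all()
    assert rank_genes(aligned.values["s1"])[0] == "g3"  # removed first
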