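import numpy as np
import pandas as pd
import pytest

from phyloendemism import (
    OccupancyTable,
    PressureGrid,
    aggregate_over_trees,
    clade_contribution,
    cumulative_capture,
    edr,
    forest_cell_metric,
    grid_pd,
    hipe,
    hipe_pe_ratio,
    hite,
    parse_newick,
    pe,
    residual_pd,
    species_scores,
    te,
    weighted_endemism,
)
import oracles


def occ_as_dict(occ):
    return {s: set(occ.cells_of(s)) for s in occ.species}


def hf_as_dict(grid):
    return {c: grid.hf(c) for c in grid.cells}


class TestGridPd:
    def test_cell_with_all_tips_scores_total_pd(self):
        t = parse_newick("((A:1,B:1):2,C:4);")
        occ = OccupancyTable([("A", "c"), ("B", "c"), ("C", "c")])
        assert grid_pd(t, occ)["c"] == t.total_pd()

    def test_single_species_cell_scores_terminal_branch(self):
        t = parse_newick("((A:1,B:1):2,C:4);")
        occ = OccupancyTable([("A", "c1"), ("A", "c2"), ("B", "c1")])
        m = grid_pd(t, occ)
        assert m["c2"] == 1.0  # A's TBL only, despite the 2 MY stem

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_per_cell_subtree_oracle(self, instance, seed):
        tree, occ, _ = instance(seed)
        expected = oracles.grid_pd(tree.to_newick(), occ_as_dict(occ))
        assert grid_pd(tree, occ).to_dict() == pytest.approx(expected)


class TestResidualPd:
    def test_exactly_linear_relationship_gives_zero_residuals(self):
        rich = pd.Series({f"c{i}": float(i + 1) for i in range(6)})
        pd_map = 3.0 * rich + 2.0
        resid = residual_pd(pd_map, rich)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero(self):
        rng = np.random.Generator(np.random.PCG64(1))
        rich = pd.Series(rng.integers(1, 30, 25).astype(float),
                         index=[f"c{i}" for i in range(25)])
        pd_map = 5 * rich + rng.normal(0, 10, 25)
        assert residual_pd(pd_map, rich).sum() == pytest.approx(0.0, abs=1e-8)

    def test_matches_closed_form_normal_equations(self):
        # five cells worked by hand: slope = cov/var, intercept = ybar - b*xbar
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 3.0, 5.0, 4.0, 6.0])
        b = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        a = y.mean() - b * x.mean()
        expected = y - (a + b * x)
        cells = [f"c{i}" for i in range(5)]
        resid = residual_pd(pd.Series(y, index=cells), pd.Series(x, index=cells))
        assert np.allclose(resid.loc[cells], expected)

    def test_constant_richness_rejected(self):
        cells = ["a", "b", "c"]
        with pytest.raises(ValueError):
            residual_pd(
                pd.Series([1.0, 2, 3], index=cells),
                pd.Series([4.0, 4, 4], index=cells),
            )


class TestWeightedEndemism:
    def test_single_cell_endemic_alone_scores_one(self):
        occ = OccupancyTable([("s", "c")])
        assert weighted_endemism(occ)["c"] == 1.0

    def test_each_species_contributes_one_in_total(self, instance):
        _, occ, _ = instance(2)
        assert weighted_endemism(occ).sum() == pytest.approx(len(occ.species))

    def test_matches_double_loop_oracle(self, instance):
        _, occ, _ = instance(3)
        expected = {}
        for sp in occ.species:
            for c in occ.cells_of(sp):
                expected[c] = expected.get(c, 0.0) + 1 / occ.range_size(sp)
        assert weighted_endemism(occ).to_dict() == pytest.approx(expected)


class TestEdr:
    def test_all_species_in_one_shared_cell(self):
        t = parse_newick("((A:1,B:1):2,C:4);")
        occ = OccupancyTable([("A", "c"), ("B", "c"), ("C", "c")])
        assert edr(t, occ)["c"] == pytest.approx(t.total_pd())

    def test_toy_hand_computation(self):
        # ED: A = 2, B = 2, C = 4; A in {c1}, B in {c1,c2}, C in {c2}
        t = parse_newick("((A:1,B:1):2,C:4);")
        occ = OccupancyTable([("A", "c1"), ("B", "c1"), ("B", "c2"), ("C", "c2")])
        m = edr(t, occ)
        assert m["c1"] == pytest.approx(2 + 1)
        assert m["c2"] == pytest.approx(1 + 4)

    def test_conserves_total_mapped_pd(self, instance):
        tree, occ, _ = instance(4)
        assert edr(tree, occ).sum() == pytest.approx(tree.total_pd(), rel=1e-9)


class TestPeAndHipe:
    def test_branch_split_equally_between_two_cells(self):
        t = parse_newick("(A:10);")
        occ = OccupancyTable([("A", "c1"), ("A", "c2")])
        m = pe(t, occ)
        assert m["c1"] == m["c2"] == 5.0

    def test_branch_in_one_cell_keeps_full_length(self):
        t = parse_newick("(A:10);")
        occ = OccupancyTable([("A", "only")])
        assert pe(t, occ)["only"] == 10.0

    def test_worked_example_focal_cell(self, worked_example):
        forest, occ, grid = worked_example
        pe_map = forest_cell_metric(forest, lambda t: pe(t, occ))
        hipe_map = forest_cell_metric(forest, lambda t: hipe(t, occ, grid))
        assert pe_map["focal"] == pytest.approx(10.0)  # 5 MY from each branch
        assert hipe_map["focal"] == pytest.approx(10 * 0.2 / 1.2 + 5.0)
        # redistributed mass lands in the pristine cell
        assert hipe_map["pristine"] > pe_map["pristine"]

    def test_hipe_equals_pe_under_constant_pressure(self, instance):
        tree, occ, grid = instance(5)
        flat = PressureGrid({c: 30.0 for c in grid.cells})
        assert np.allclose(
            hipe(tree, occ, flat).sort_index(), pe(tree, occ).sort_index()
        )

    @pytest.mark.parametrize("seed", [6, 7])
    def test_match_brute_force_loops(self, instance, seed):
        tree, occ, grid = instance(seed)
        nwk = tree.to_newick()
        assert pe(tree, occ).to_dict() == pytest.approx(
            oracles.pe(nwk, occ_as_dict(occ))
        )
        assert hipe(tree, occ, grid).to_dict() == pytest.approx(
            oracles.hipe(nwk, occ_as_dict(occ), hf_as_dict(grid))
        )

    def test_moving_weight_away_never_raises_hipe(self, instance):
        # lowering one cell's HF weight (raising its HF) cannot raise its HIPE
        tree, occ, grid = instance(8)
        base = hipe(tree, occ, grid)
        cell = base.idxmax()
        hf = hf_as_dict(grid)
        if hf[cell] >= 12:
            pytest.skip("cell already at minimum weight")
        hf[cell] = 50.0
        perturbed = hipe(tree, occ, PressureGrid(hf))
        assert perturbed[cell] <= base[cell] + 1e-12

    def test_terminal_component_recovers_te_times_range(self, instance):
        tree, occ, _ = instance(9)
        te_map = te(tree, occ)
        tbl = tree.terminal_branch_lengths()
        for sp in te_map.index:
            assert te_map[sp] * occ.range_size(sp) == pytest.approx(tbl[sp])


class TestHipePeRatio:
    def test_worked_example_focal_ratio_is_two_thirds(self, worked_example):
        forest, occ, grid = worked_example
        pe_map = forest_cell_metric(forest, lambda t: pe(t, occ))
        hipe_map = forest_cell_metric(forest, lambda t: hipe(t, occ, grid))
        ratios = hipe_pe_ratio(hipe_map, pe_map, grid, "very_high")
        # focal: (1.667 + 5) / (5 + 5); branch A alone would give 1/3
        assert ratios["focal"] == pytest.approx((10 * 0.2 / 1.2 + 5) / 10)
        assert (ratios <= 1 + 1e-12).all()

    def test_single_branch_ratio_matches_worked_values(self):
        t = parse_newick("(A:10);")
        occ = OccupancyTable([("A", "focal"), ("A", "pristine")])
        grid = PressureGrid({"focal": 20.0, "pristine": 0.0})
        ratios = hipe_pe_ratio(
            hipe(t, occ, grid), pe(t, occ), grid, "very_high"
        )
        assert ratios["focal"] == pytest.approx((10 * 0.2 / 1.2) / 5)  # = 1/3

    def test_zero_pressure_cells_gain(self, instance):
        tree, occ, grid = instance(10)
        ratios = hipe_pe_ratio(
            hipe(tree, occ, grid), pe(tree, occ), grid, "none"
        )
        assert (ratios >= 1 - 1e-12).all()

    def test_wholly_very_high_branch_set_gives_unit_ratio(self):
        t = parse_newick("(A:10);")
        occ = OccupancyTable([("A", "c1"), ("A", "c2")])
        grid = PressureGrid({"c1": 20.0, "c2": 40.0})
        ratios = hipe_pe_ratio(hipe(t, occ, grid), pe(t, occ), grid, "very_high")
        assert np.allclose(ratios, 1.0)


class TestCladeContribution:
    def test_single_clade_gets_proportion_one(self):
        out = clade_contribution({"x": pd.Series({"c": 3.0})})
        assert out.loc["c", "x"] == 1.0

    def test_equal_values_split_evenly_and_rows_sum_to_one(self):
        a = pd.Series({"c1": 2.0, "c2": 1.0})
        b = pd.Series({"c1": 2.0})
        out = clade_contribution({"a": a, "b": b})
        assert out.loc["c1"].tolist() == [0.5, 0.5]
        assert np.allclose(out.sum(axis=1), 1.0)


class TestCumulativeCapture:
    def test_all_mass_in_one_cell(self):
        bands = cumulative_capture(
            pd.Series({"big": 10.0, "zero": 0.0}), [0.25, 0.5, 1.0]
        )
        assert bands["big"] == 0.25

    def test_uniform_values_fill_bands_one_per_cell(self):
        m = pd.Series({f"c{i}": 1.0 for i in range(10)})
        bands = cumulative_capture(m, [i / 10 for i in range(1, 11)])
        assert sorted(bands.values) == [i / 10 for i in range(1, 11)]

    def test_matches_prefix_sum_oracle(self, instance):
        tree, occ, _ = instance(11)
        m = pe(tree, occ)
        fractions = [0.2, 0.5, 1.0]
        bands = cumulative_capture(m, fractions)
        ranked = sorted(m.index, key=lambda c: (-m[c], c))
        running = 0.0
        for c in ranked:
            want = next((f for f in fractions if running < f - 1e-12), np.nan)
            running += m[c] / m.sum()
            assert bands[c] == want or (np.isnan(bands[c]) and np.isnan(want))


class TestSpeciesScores:
    def test_te_worked_example(self):
        t = parse_newick("(A:10);")
        occ = OccupancyTable([("A", "c1"), ("A", "c2")])
        assert te(t, occ)["A"] == 5.0

    def test_te_single_cell_endemic_equals_tbl(self):
        t = parse_newick("((A:3,B:1):1,C:2);")
        occ = OccupancyTable([("A", "c"), ("B", "c"), ("C", "c")])
        assert te(t, occ)["A"] == 3.0

    def test_hite_worked_example(self, worked_example):
        forest, occ, grid = worked_example
        tree_h = next(t for t in forest if "H" in t.tips)
        assert hite(tree_h, occ, grid)["H"] == pytest.approx(10 / 1.2)

    def test_hite_reduces_to_te_without_pressure(self, instance):
        tree, occ, grid = instance(12)
        flat = PressureGrid({c: 0.0 for c in grid.cells})
        assert np.allclose(hite(tree, occ, flat), te(tree, occ))

    def test_hite_is_five_times_te_under_uniform_very_high(self, instance):
        tree, occ, grid = instance(13)
        vh = PressureGrid({c: 20.0 for c in grid.cells})
        assert np.allclose(hite(tree, occ, vh), 5 * te(tree, occ))

    @pytest.mark.parametrize("seed", [14, 15])
    def test_te_hite_match_elementwise_oracles(self, instance, seed):
        tree, occ, grid = instance(seed)
        nwk = tree.to_newick()
        assert te(tree, occ).to_dict() == pytest.approx(
            oracles.te(nwk, occ_as_dict(occ))
        )
        assert hite(tree, occ, grid).to_dict() == pytest.approx(
            oracles.hite(nwk, occ_as_dict(occ), hf_as_dict(grid))
        )

    def test_score_table_identities_and_ranking(self, instance):
        tree, occ, grid = instance(16)
        table = species_scores(tree, occ, grid)
        assert np.allclose(table["te"], table["tbl"] / table["range"])
        assert np.allclose(
            table["hite"], table["tbl"] / table["hp_weighted_range"]
        )
        ratio = table["hite"] / table["te"]
        assert ((ratio >= 1 - 1e-12) & (ratio <= 5 + 1e-12)).all()
        ranked = table.sort_values("hite_rank")
        assert ranked["hite"].is_monotonic_decreasing


class TestAggregation:
    def test_single_tree_is_identity(self):
        s = pd.Series({"c": 2.0}, name="m")
        out = aggregate_over_trees([parse_newick("(A:1,B:1);")], lambda t: s)
        assert out.loc["c", "median"] == 2.0

    def test_median_conventions(self):
        trees = [parse_newick("(A:1,B:1);")] * 4
        out3 = aggregate_over_trees(
            trees[:3], lambda t, it=iter([1.0, 2.0, 9.0]): pd.Series({"c": next(it)})
        )
        assert out3.loc["c", "median"] == 2.0
        out4 = aggregate_over_trees(
            trees, lambda t, it=iter([1.0, 2.0, 3.0, 4.0]): pd.Series({"c": next(it)})
        )
        assert out4.loc["c", "median"] == 2.5

    def test_sparse_keys_are_flagged_and_dropped(self, caplog):
        trees = [parse_newick("(A:1,B:1);")] * 4
        series = iter(
            [
                pd.Series({"c": 1.0, "rare": 7.0}),
                pd.Series({"c": 2.0}),
                pd.Series({"c": 3.0}),
                pd.Series({"c": 4.0}),
            ]
        )
        with caplog.at_level("WARNING"):
            out = aggregate_over_trees(trees, lambda t: next(series))
        assert "rare" not in out.index
        assert out.loc["c", "n_trees"] == 4


class TestForestSummation:
    def test_forest_metric_is_sum_of_clade_metrics(self):
        t1 = parse_newick("(A:1,B:2);")
        t2 = parse_newick("(C:5,D:5);")
        occ = OccupancyTable(
            [("A", "c1"), ("B", "c1"), ("C", "c1"), ("D", "c2")]
        )
        combined = forest_cell_metric([t1, t2], lambda t: pe(t, occ))
        assert combined["c1"] == pytest.approx(
            pe(t1, occ)["c1"] + pe(t2, occ)["c1"]
        )
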