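import numpy as np
import pytest

from spasne import (
    CellResult,
    EmbedConfig,
    ScreeningGrid,
    choose_cell,
    compute_threshold,
    distance_correlation,
    final_embedding,
    fine_screen,
    preprocess,
    repeat_seed,
    rough_screen,
    screen_cell,
    select_fine_grid,
    select_optimal_repeat,
    tsne_embed,
)


@pytest.fixture(scope="module")
def screen_data(small_fixture):
    X = preprocess(small_fixture.counts).values
    return X, small_fixture.coords.values


@pytest.fixture
def screen_cfg():
    return EmbedConfig(perplexity=10, max_iter=150, momentum_switch_iter=60,
                       exaggeration_iters=60, seed=0)


class TestSelectOptimalRepeat:
    def test_injected_values_hand_arithmetic(self):
        # products: .5*.4=.20, .6*.3=.18, .55*.5=.275 -> third repeat wins
        metrics = [(0.5, 0.4), (0.6, 0.3), (0.55, 0.5)]
        rg, rs, std, idx = select_optimal_repeat(metrics, r_thres=0.2)
        assert (rg, rs, idx) == (0.55, 0.5, 2)
        assert std == pytest.approx(np.std([0.5, 0.6, 0.55]))

    def test_threshold_zeroes_failing_repeats(self):
        metrics = [(0.15, 0.9), (0.1, 0.8)]
        rg, rs, std, _ = select_optimal_repeat(metrics, r_thres=0.2)
        assert rg == 0.0 and rg * rs == 0.0
        assert std == 0.0  # all thresholded values are zero

    def test_threshold_is_strict_inequality(self):
        # r_g equal to the threshold is zeroed (rule is r_g <= r_thres)
        rg, _, _, _ = select_optimal_repeat([(0.2, 0.5)], r_thres=0.2)
        assert rg == 0.0

    def test_single_repeat_zero_std(self):
        rg, rs, std, idx = select_optimal_repeat([(0.7, 0.6)], r_thres=0.1)
        assert (rg, rs, std, idx) == (0.7, 0.6, 0.0, 0)

    def test_std_mode_switch(self):
        metrics = [(0.15, 0.5), (0.6, 0.5)]
        _, _, std_thr, _ = select_optimal_repeat(metrics, 0.2, std_on_thresholded=True)
        _, _, std_raw, _ = select_optimal_repeat(metrics, 0.2, std_on_thresholded=False)
        assert std_thr == pytest.approx(np.std([0.0, 0.6]))
        assert std_raw == pytest.approx(np.std([0.15, 0.6]))


class TestChooseCell:
    def test_injected_table_hand_arithmetic(self):
        cells = [
            CellResult(5, 1, 0.3, 0.4, 0.1),
            CellResult(5, 2, 0.35, 0.3, 0.05),
            CellResult(10, 1, 0.2, 0.5, 0.0),
            CellResult(10, 2, 0.33, 0.35, 0.2),
        ]
        # scores: .12*e^.9=.2951, .105*e^.95=.2715, .10*e^1=.2718, .1155*e^.8=.2571
        assert choose_cell(cells) == (5, 1)
        for c in cells:
            assert c.score == pytest.approx(
                c.r_g_opt * c.r_s_opt * np.exp(1 - c.std)
            )

    def test_tie_broken_by_smaller_alpha_then_beta(self):
        cells = [CellResult(10, 5, 0.5, 0.5, 0.0), CellResult(5, 8, 0.5, 0.5, 0.0)]
        assert choose_cell(cells) == (5, 8)
        cells = [CellResult(5, 8, 0.5, 0.5, 0.0), CellResult(5, 3, 0.5, 0.5, 0.0)]
        assert choose_cell(cells) == (5, 3)

    def test_all_zero_scores_fall_back_to_defaults(self, caplog):
        cells = [CellResult(2, 1, 0.0, 0.4, 0.1), CellResult(5, 1, 0.0, 0.5, 0.2)]
        with caplog.at_level("WARNING", logger="spasne"):
            assert choose_cell(cells) == (10.0, 5.0)
        assert any("fall" in r.message for r in caplog.records)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            choose_cell([])


class TestSeedSchedule:
    def test_arithmetic_and_stable(self):
        assert repeat_seed(0, "threshold", 0, 0) == 0
        assert repeat_seed(0, "threshold", 0, 3) == 3
        assert repeat_seed(7, "rough", 2, 1) == 7 + 100_000 + 2_000 + 1
        assert repeat_seed(7, "fine", 0, 0) == 7 + 200_000
        assert 0 <= repeat_seed(2**31 - 1, "final", 500, 99) < 2**31

    def test_distinct_across_cells_and_repeats(self):
        seeds = {repeat_seed(0, s, c, r)
                 for s in ("threshold", "rough", "fine", "final")
                 for c in range(5) for r in range(10)}
        assert len(seeds) == 4 * 5 * 10


class TestThreshold:
    def test_single_repeat_equals_that_run(self, screen_data, screen_cfg):
        from dataclasses import replace
        X, _ = screen_data
        thres = compute_threshold(X, screen_cfg, n_repeats=1)
        res = tsne_embed(X, replace(screen_cfg, seed=repeat_seed(0, "threshold", 0, 0)))
        assert thres == pytest.approx(distance_correlation(X, res.Y))

    def test_non_decreasing_in_repeats(self, screen_data, screen_cfg):
        X, _ = screen_data
        t1 = compute_threshold(X, screen_cfg, n_repeats=1)
        t3 = compute_threshold(X, screen_cfg, n_repeats=3)
        assert t3 >= t1

    def test_equals_max_of_individual_runs(self, screen_data, screen_cfg):
        from dataclasses import replace
        X, _ = screen_data
        vals = []
        for r in range(3):
            cfg = replace(screen_cfg, seed=repeat_seed(0, "threshold", 0, r))
            vals.append(distance_correlation(X, tsne_embed(X, cfg).Y))
        assert compute_threshold(X, screen_cfg, 3) == pytest.approx(max(vals))


class TestGridScreens:
    def test_rough_table_shape_and_recomputation(self, screen_data, screen_cfg):
        X, Z = screen_data
        grid = ScreeningGrid([5.0, 10.0], [1.0, 5.0], repeats=2)
        table = rough_screen(X, Z, grid, r_thres=0.0, cfg=screen_cfg)
        assert len(table) == 4
        # cell-by-cell recomputation under the same seed schedule
        for idx, cell in enumerate(table):
            rg, rs, std = screen_cell(X, Z, cell.alpha, cell.beta, 2, 0.0,
                                      screen_cfg, stage="rough", cell_index=idx)
            assert (rg, rs, std) == (cell.r_g_opt, cell.r_s_opt, cell.std)
            assert cell.score == pytest.approx(rg * rs)

    def test_single_cell_grid_reduces_to_screen_cell(self, screen_data, screen_cfg):
        X, Z = screen_data
        grid = ScreeningGrid([10.0], [5.0], repeats=2)
        table = rough_screen(X, Z, grid, 0.0, screen_cfg)
        rg, rs, std = screen_cell(X, Z, 10.0, 5.0, 2, 0.0, screen_cfg,
                                  stage="rough", cell_index=0)
        assert len(table) == 1
        assert (table[0].r_g_opt, table[0].r_s_opt, table[0].std) == (rg, rs, std)

    def test_fine_screen_chosen_attains_max(self, screen_data, screen_cfg):
        X, Z = screen_data
        grid = ScreeningGrid([5.0, 10.0], [2.0, 5.0], repeats=2)
        report = fine_screen(X, Z, grid, r_thres=0.0, cfg=screen_cfg)
        best = max(c.score for c in report.cells)
        chosen = [c for c in report.cells
                  if (c.alpha, c.beta) == report.chosen][0]
        assert chosen.score == pytest.approx(best)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ScreeningGrid([], [1.0], repeats=1)


class TestFineGridSelection:
    def test_bounding_box_with_one_step_expansion(self):
        cells = [CellResult(a, b, 0, 0, 0, score=0.0)
                 for a in (2, 5, 10, 20) for b in (1, 5, 10)]
        for c in cells:
            c.score = 1.0 if (c.alpha, c.beta) == (5, 5) else 0.1
        grid = select_fine_grid(cells, repeats=3)
        # box around (5,5) expanded one rough step: alpha 2..10, beta 1..10
        assert min(grid.alphas) == 2.0 and max(grid.alphas) == 10.0
        assert min(grid.betas) == 1.0 and max(grid.betas) == 10.0
        assert grid.repeats == 3


class TestFinalEmbedding:
    def test_single_repeat_returns_that_run(self, screen_data, screen_cfg):
        X, Z = screen_data
        res, scores = final_embedding(X, Z, (10.0, 5.0), 1, screen_cfg)
        assert res.Y.shape == (X.shape[0], 2)
        assert scores.r_g == pytest.approx(distance_correlation(X, res.Y))

    def test_winner_beats_every_repeat(self, screen_data, screen_cfg):
        from dataclasses import replace
        from spasne import spasne_embed
        X, Z = screen_data
        res, _ = final_embedding(X, Z, (10.0, 5.0), 3, screen_cfg)
        win = distance_correlation(X, res.Y) * distance_correlation(Z, res.Y)
        for r in range(3):
            cfg = replace(screen_cfg, alpha=10.0, beta=5.0,
                          seed=repeat_seed(0, "final", 0, r))
            other = spasne_embed(X, Z, cfg)
            prod = (distance_correlation(X, other.Y)
                    * distance_correlation(Z, other.Y))
            assert win >= prod - 1e-12
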