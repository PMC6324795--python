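import itertools

import numpy as np
import pandas as pd
import pytest

from is3sim.cell import ScenarioResult
from is3sim.input_gen import InputScenario
from is3sim.sweep import (
    SweepGrid,
    assign_pool,
    cbdr_matrix,
    cbdr_params_to_pixel,
    cbdr_pixel_to_params,
    cbdr_render,
    ei_metric_1,
    ei_metric_2,
    enumerate_grid,
    find_representative,
    scenario_seed,
)
from is3sim.trace_metrics import IvlAssessment


class TestGridEnumeration:
    def test_axis_cardinalities(self):
        g = SweepGrid()
        assert len(g.f_e_values) == 7
        assert len(g.f_i_values) == 11
        assert len(g.n_e_values) == 85
        assert len(g.n_i_values) == 86
        assert g.core_size == 562_870

    def test_single_value_ranges_give_one_scenario(self):
        g = SweepGrid(
            f_e_values=(5.0,), f_i_values=(10.0,), n_e_values=(18,), n_i_values=(4,),
            variants=("AType+",), common_modes=((1, 1),),
        )
        scenarios = list(enumerate_grid(g))
        assert len(scenarios) == 1
        variant, sc = scenarios[0]
        assert (variant, sc.f_e, sc.n_i) == ("AType+", 5.0, 4)

    def test_ordering_is_rate_major_count_minor(self):
        g = SweepGrid(
            f_e_values=(0.0, 5.0), f_i_values=(0.0,), n_e_values=(18, 36),
            n_i_values=(4,), variants=("AType+",), common_modes=((9, 4),),
        )
        coords = [(sc.f_e, sc.n_e) for _, sc in enumerate_grid(g)]
        assert coords == [(0.0, 18), (0.0, 36), (5.0, 18), (5.0, 36)]

    def test_malformed_ranges_rejected(self):
        with pytest.raises(ValueError):
            SweepGrid(f_e_values=(5.0, 5.0))
        with pytest.raises(ValueError):
            SweepGrid(n_e_values=())

    def test_seed_is_deterministic_and_distinct(self):
        a = scenario_seed("AType+", 5, 10, 18, 4, 9, 4)
        b = scenario_seed("AType+", 5, 10, 18, 4, 9, 4)
        c = scenario_seed("AType+", 5, 10, 36, 4, 9, 4)
        assert a == b != c
        assert 0 <= a < 2**31


class TestEiMetrics:
    @pytest.mark.parametrize(
        "coords, expected",
        [
            ((30.0, 0.0, 1530, 0), 1.0),
            ((0.0, 100.0, 0, 344), -1.0),
            ((15.0, 50.0, 18 * 85 // 2, 172), 0.0),
        ],
    )
    def test_normalized_metric_anchors(self, coords, expected):
        f_e, f_i, n_e, n_i = coords
        sc = InputScenario(f_e, f_i, n_e, n_i)
        assert ei_metric_1(sc) == pytest.approx(expected, abs=1e-12)

    def test_normalized_metric_is_bounded_on_the_grid(self):
        g = SweepGrid()
        for f_e, f_i in itertools.product(g.f_e_values, g.f_i_values):
            for n_e, n_i in ((18, 4), (18, 344), (1530, 4), (1530, 344)):
                v = ei_metric_1(InputScenario(f_e, f_i, n_e, n_i), g)
                assert -1.0 <= v <= 1.0

    @pytest.mark.parametrize(
        "coords, expected",
        [((10.0, 50.0, 100, 20), 0.0), ((20.0, 60.0, 900, 100), 12_000.0)],
    )
    def test_cumulative_rate_metric(self, coords, expected):
        f_e, f_i, n_e, n_i = coords
        assert ei_metric_2(InputScenario(f_e, f_i, n_e, n_i)) == expected

    def test_cumulative_rate_metric_antisymmetry(self):
        a = ei_metric_2(InputScenario(20.0, 90.0, 90, 40))
        b = ei_metric_2(InputScenario(f_e=20.0, f_i=90.0, n_e=180, n_i=40))
        # swapping which side carries the larger product flips the sign
        assert np.sign(a) != np.sign(b) or a == 0


class TestPoolAssignment:
    @pytest.mark.parametrize(
        "coords, label",
        [
            ((10.0, 30.0, 400, 100), "LLLL"),
            ((30.0, 100.0, 1530, 344), "HHHH"),
            ((15.0, 30.0, 400, 100), "LLLL"),
            ((20.0, 30.0, 400, 100), "LLLH"),
            ((10.0, 60.0, 400, 100), "LLHL"),
            ((10.0, 30.0, 792, 100), "LHLL"),
            ((10.0, 30.0, 400, 176), "HLLL"),
        ],
    )
    def test_letter_order_is_ni_ne_fi_fe(self, coords, label):
        f_e, f_i, n_e, n_i = coords
        assert assign_pool(InputScenario(f_e, f_i, n_e, n_i)) == label

    def test_gap_values_are_rejected(self):
        with pytest.raises(ValueError, match="no Low/High range"):
            assign_pool(InputScenario(17.0, 30.0, 400, 100))
        with pytest.raises(ValueError, match="no Low/High range"):
            assign_pool(InputScenario(10.0, 30.0, 774, 100))


def _records(rows):
    cols = ["f_e", "f_i", "n_e", "n_i", "k_e", "k_i", "seed", "state"]
    return pd.DataFrame(rows, columns=cols)


def _runner(outcomes):
    """Stub scenario runner: pops verdicts keyed by (f_e, n_e) per call."""
    calls = []

    def run(sc):
        calls.append(sc)
        verdicts = outcomes[(sc.f_e, sc.n_e)]
        state = verdicts.pop(0) if verdicts else "IVL"
        ivl = IvlAssessment(3 if state == "IVL" else 0, state)
        return ScenarioResult(sc, None, None, None, ivl)

    run.calls = calls
    return run


class TestFindRepresentative:
    def test_failing_candidate_is_skipped_and_next_one_returned(self):
        records = _records([
            (5.0, 30.0, 144, 40, 9, 4, 11, "IVL"),
            (5.0, 30.0, 360, 40, 9, 4, 12, "IVL"),
        ])
        outcomes = {
            (5.0, 144): ["IVL", "IVL", "NIVL"],  # fails on 3rd reseed
            (5.0, 360): ["IVL"] * 10,
        }
        rep = find_representative(records, _runner(outcomes), n_confirm=10)
        assert rep is not None and rep.n_e == 360 and rep.seed == 12

    def test_candidates_visited_in_search_order(self):
        records = _records([
            (10.0, 30.0, 144, 40, 9, 4, 2, "IVL"),
            (5.0, 50.0, 144, 40, 9, 4, 3, "IVL"),
        ])
        run = _runner({(5.0, 144): ["IVL"] * 10, (10.0, 144): ["IVL"] * 10})
        rep = find_representative(records, run, n_confirm=2)
        assert rep.f_e == 5.0  # lower f_e wins despite row order

    def test_exhausted_pool_returns_none(self):
        records = _records([(5.0, 30.0, 144, 40, 9, 4, 1, "IVL")])
        rep = find_representative(
            records, _runner({(5.0, 144): ["NIVL"] * 10}), n_confirm=10
        )
        assert rep is None

    def test_pool_without_ivl_records_returns_none(self):
        records = _records([(5.0, 30.0, 144, 40, 9, 4, 1, "NIVL")])
        rep = find_representative(records, _runner({}), n_confirm=10)
        assert rep is None


@pytest.fixture()
def tiny_grid():
    return SweepGrid(
        f_e_values=(0.0, 5.0), f_i_values=(0.0, 10.0, 20.0),
        n_e_values=(18, 36, 54), n_i_values=(4, 8),
        variants=("AType+",), common_modes=((9, 4),),
    )


@pytest.fixture()
def tiny_results(tiny_grid):
    rows = []
    for _, sc in enumerate_grid(tiny_grid):
        rows.append({
            "f_e": sc.f_e, "f_i": sc.f_i, "n_e": sc.n_e, "n_i": sc.n_i,
            "ivl_metric": int(sc.n_e // 18 - 2 * (sc.f_e > 0)),
        })
    return pd.DataFrame(rows)


class TestCbdr:
    def test_matrix_shape_follows_axis_nesting(self, tiny_grid, tiny_results):
        mat = cbdr_matrix(tiny_results, tiny_grid)
        assert mat.shape == (2 * 3, 3 * 2)

    def test_pixel_round_trip_identity(self, tiny_grid):
        for row in range(6):
            for col in range(6):
                p = cbdr_pixel_to_params(tiny_grid, row, col)
                assert cbdr_params_to_pixel(
                    tiny_grid, p["f_e"], p["n_e"], p["f_i"], p["n_i"]
                ) == (row, col)

    def test_inner_step_changes_count_not_rate(self, tiny_grid):
        a = cbdr_pixel_to_params(tiny_grid, 0, 0)
        b = cbdr_pixel_to_params(tiny_grid, 1, 0)
        assert b["n_e"] - a["n_e"] == 18 and b["f_e"] == a["f_e"]
        c = cbdr_pixel_to_params(tiny_grid, 0, 1)
        assert c["n_i"] - a["n_i"] == 4 and c["f_i"] == a["f_i"]

    def test_pixel_values_match_records(self, tiny_grid, tiny_results):
        mat = cbdr_matrix(tiny_results, tiny_grid)
        row = tiny_results.iloc[7]
        r, c = cbdr_params_to_pixel(tiny_grid, row.f_e, row.n_e, row.f_i, row.n_i)
        assert mat[r, c] == row.ivl_metric

    def test_incomplete_grid_rejected(self, tiny_grid, tiny_results):
        with pytest.raises(ValueError, match="missing"):
            cbdr_matrix(tiny_results.iloc[:-2], tiny_grid)

    def test_render_writes_png_and_sidecar(self, tiny_grid, tiny_results, tmp_path):
        png = tmp_path / "cbdr.png"
        cbdr_render(tiny_results, tiny_grid, png_path=png)
        assert png.exists()
        assert (tmp_path / "cbdr.json").exists()
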