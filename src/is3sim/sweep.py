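"""Grid enumeration, E/I balance metrics, pool division, representatives, CBDR.

The production parameter space is a 4-D grid (excitatory rate 0-30 Hz by 5,
inhibitory rate 0-100 Hz by 10, excitatory synapses 18-1530 by 18, inhibitory
synapses 4-344 by 4), crossed with two model variants and four common-input
modes - 4,502,960 ten-second simulations in full. The full grid is
enumerable here; executing it is cluster work, so sweeps run on configurable
(typically coarsened) grids.

Pools split each parameter into Low/High halves, labelled in the order
(N_I, N_E, f_I, f_E); e.g. LLLL is low everything. Two scalar balance
metrics summarize a scenario: a normalized difference bounded in [-1, 1]
and the raw difference of cumulative spike rates f_E*N_E - f_I*N_I
(negative = inhibitory-dominant).
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from .cell import CellModel, ScenarioResult
from .input_gen import InputScenario

__all__ = [
    "SweepGrid", "PoolLabel", "enumerate_grid", "scenario_seed",
    "ei_metric_1", "ei_metric_2", "assign_pool", "run_sweep",
    "find_representative", "cbdr_matrix", "cbdr_render",
]


def _inclusive_range(lo: float, step: float, hi: float) -> tuple:
    n = int(round((hi - lo) / step)) + 1
    return tuple(lo + step * i for i in range(n))


@dataclass(frozen=True)
class SweepGrid:
    """Axis values and maxima of the 4-D input grid."""

    f_e_values: tuple = _inclusive_range(0, 5, 30)        # 7 values
    f_i_values: tuple = _inclusive_range(0, 10, 100)      # 11 values
    n_e_values: tuple = _inclusive_range(18, 18, 1530)    # 85 values
    n_i_values: tuple = _inclusive_range(4, 4, 344)       # 86 values
    variants: tuple = ("AType+", "AType-")
    common_modes: tuple = ((1, 1), (9, 1), (1, 4), (9, 4))  # (k_e, k_i)
    f_e_max: float = 30.0
    f_i_max: float = 100.0
    n_e_max: int = 1530
    n_i_max: int = 344

    def __post_init__(self) -> None:
        for name in ("f_e_values", "f_i_values", "n_e_values", "n_i_values"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be non-empty and strictly increasing")

    @property
    def core_size(self) -> int:
        return (len(self.f_e_values) * len(self.f_i_values)
                * len(self.n_e_values) * len(self.n_i_values))

    @property
    def total_size(self) -> int:
        return self.core_size * len(self.variants) * len(self.common_modes)

    def reduced(self, f_stride: int = 2, n_stride: int = 5) -> "SweepGrid":
        """Coarsened grid for desk-scale sweeps (same maxima)."""
        return replace(
            self,
            f_e_values=self.f_e_values[::f_stride],
            f_i_values=self.f_i_values[::f_stride],
            n_e_values=self.n_e_values[::n_stride],
            n_i_values=self.n_i_values[::n_stride],
        )


def scenario_seed(variant: str, f_e, f_i, n_e, n_i, k_e, k_i, replicate: int = 0) -> int:
    """Deterministic seed from a scenario's coordinates (stable across runs)."""
    key = f"{variant}|{f_e:g}|{f_i:g}|{n_e}|{n_i}|{k_e}|{k_i}|{replicate}"
    return zlib.crc32(key.encode()) % (2**31)


def enumerate_grid(grid: SweepGrid) -> Iterator[tuple[str, InputScenario]]:
    """Yield (variant, scenario) over the full grid in deterministic order.

    Axis nesting follows the representative-search order: excitatory rate,
    then inhibitory rate, then excitatory count, then inhibitory count,
    ascending; variants and common modes are outermost.
    """
    for variant in grid.variants:
        for k_e, k_i in grid.common_modes:
            for f_e, f_i, n_e, n_i in itertools.product(
                grid.f_e_values, grid.f_i_values, grid.n_e_values, grid.n_i_values
            ):
                yield variant, InputScenario(
                    f_e=f_e, f_i=f_i, n_e=int(n_e), n_i=int(n_i),
                    k_e=k_e, k_i=k_i,
                    seed=scenario_seed(variant, f_e, f_i, n_e, n_i, k_e, k_i),
                )


def ei_metric_1(scenario: InputScenario, grid: SweepGrid | None = None) -> float:
    """Normalized E-I difference in [-1, 1] (+1 purely excitatory-dominant)."""
    g = grid or SweepGrid()
    return 0.5 * (
        scenario.n_e / g.n_e_max + scenario.f_e / g.f_e_max
        - scenario.n_i / g.n_i_max - scenario.f_i / g.f_i_max
    )


def ei_metric_2(scenario: InputScenario) -> float:
    """Cumulative spike-rate difference f_E*N_E - f_I*N_I (Hz*synapses)."""
    return scenario.f_e * scenario.n_e - scenario.f_i * scenario.n_i


# ---------------------------------------------------------------------------
# Pool division
# ---------------------------------------------------------------------------

#: (low_max, high_min, high_max) per parameter; values strictly between
#: low_max and high_min lie off-grid and are rejected.
_POOL_RANGES = {
    "f_e": (15.0, 20.0, 30.0),
    "f_i": (50.0, 60.0, 100.0),
    "n_e": (765, 783, 1530),
    "n_i": (172, 176, 344),
}

PoolLabel = str  # four letters L/H ordered (N_I, N_E, f_I, f_E)


def assign_pool(scenario: InputScenario) -> PoolLabel:
    """Four-letter Low/High label in the order (N_I, N_E, f_I, f_E)."""
    letters = []
    for name, value in (
        ("n_i", scenario.n_i), ("n_e", scenario.n_e),
        ("f_i", scenario.f_i), ("f_e", scenario.f_e),
    ):
        low_max, high_min, high_max = _POOL_RANGES[name]
        if value <= low_max:
            letters.append("L")
        elif high_min <= value <= high_max:
            letters.append("H")
        else:
            raise ValueError(f"{name}={value} falls in no Low/High range")
    return "".join(letters)


# ---------------------------------------------------------------------------
# Sweep execution
# ---------------------------------------------------------------------------

def run_sweep(
    cell: CellModel,
    scenarios: Iterable[InputScenario],
    grid: SweepGrid | None = None,
    progress: Callable[[int], None] | None = None,
) -> pd.DataFrame:
    """Run scenarios on one cell and tabulate metrics, one row per scenario."""
    g = grid or SweepGrid()
    rows = []
    for i, sc in enumerate(scenarios):
        res = cell.run_scenario(sc)
        m = res.measurements
        rows.append({
            "variant": cell.variant,
            "f_e": sc.f_e, "f_i": sc.f_i, "n_e": sc.n_e, "n_i": sc.n_i,
            "k_e": sc.k_e, "k_i": sc.k_i, "seed": sc.seed,
            "mean_sub_vm": m.mean_sub_vm, "sigma_sub_vm": m.sigma_sub_vm,
            "isi_cv": m.isi_cv, "mean_spike_amp": m.mean_spike_amp,
            "n_spikes": m.n_spikes, "mean_rate_hz": res.mean_rate_hz,
            "ivl_metric": res.ivl.ivl_metric, "state": res.ivl.state,
            "pool": assign_pool(sc),
            "ei_metric_1": ei_metric_1(sc, g), "ei_metric_2": ei_metric_2(sc),
        })
        if progress is not None:
            progress(i)
    return pd.DataFrame(rows)


def find_representative(
    pool_records: pd.DataFrame,
    runner: Callable[[InputScenario], ScenarioResult],
    n_confirm: int = 10,
    max_candidates: int | None = None,
) -> InputScenario | None:
    """First IVL scenario of a pool that stays IVL over reseeded re-runs.

    Candidates are the pool's IVL records ordered by (f_e, f_i, n_e, n_i,
    seed) ascending. Each is re-simulated ``n_confirm`` times with fresh
    placement and spike-time seeds; any failure skips to the next candidate.
    Returns None when the pool is exhausted (mirrors pools with no robust
    representative).
    """
    ivl = pool_records[pool_records["state"] == "IVL"]
    ivl = ivl.sort_values(["f_e", "f_i", "n_e", "n_i", "seed"], kind="stable")
    if max_candidates is not None:
        ivl = ivl.head(max_candidates)
    for _, row in ivl.iterrows():
        ok = True
        for rep in range(1, n_confirm + 1):
            sc = InputScenario(
                f_e=row.f_e, f_i=row.f_i, n_e=int(row.n_e), n_i=int(row.n_i),
                k_e=int(row.k_e), k_i=int(row.k_i),
                seed=scenario_seed("rep", row.f_e, row.f_i, int(row.n_e),
                                   int(row.n_i), int(row.k_e), int(row.k_i), rep),
            )
            if runner(sc).ivl.state != "IVL":
                ok = False
                break
        if ok:
            return InputScenario(
                f_e=row.f_e, f_i=row.f_i, n_e=int(row.n_e), n_i=int(row.n_i),
                k_e=int(row.k_e), k_i=int(row.k_i), seed=int(row.seed),
            )
    return None


# ---------------------------------------------------------------------------
# Clutter-based dimensional reordering (CBDR)
# ---------------------------------------------------------------------------

def cbdr_matrix(
    results: pd.DataFrame, grid: SweepGrid, value: str = "ivl_metric"
) -> np.ndarray:
    """Nest the 4-D grid into a 2-D image matrix.

    Rows stack (f_E outer, N_E inner) ascending; columns stack (f_I outer,
    N_I inner). ``matrix[row, col]`` holds ``value`` for the corresponding
    grid point; raises with the list of missing points if the results do not
    cover the full rectangle.
    """
    fe_ix = {v: i for i, v in enumerate(grid.f_e_values)}
    fi_ix = {v: i for i, v in enumerate(grid.f_i_values)}
    ne_ix = {v: i for i, v in enumerate(grid.n_e_values)}
    ni_ix = {v: i for i, v in enumerate(grid.n_i_values)}
    n_rows = len(fe_ix) * len(ne_ix)
    n_cols = len(fi_ix) * len(ni_ix)
    mat = np.full((n_rows, n_cols), np.nan)
    for _, row in results.iterrows():
        r = fe_ix[row.f_e] * len(ne_ix) + ne_ix[row.n_e]
        c = fi_ix[row.f_i] * len(ni_ix) + ni_ix[row.n_i]
        mat[r, c] = row[value]
    if np.isnan(mat).any():
        missing = int(np.isnan(mat).sum())
        raise ValueError(f"results do not cover the full grid ({missing} pixels missing)")
    return mat


def cbdr_pixel_to_params(grid: SweepGrid, row: int, col: int) -> dict:
    n_ne, n_ni = len(grid.n_e_values), len(grid.n_i_values)
    return {
        "f_e": grid.f_e_values[row // n_ne],
        "n_e": grid.n_e_values[row % n_ne],
        "f_i": grid.f_i_values[col // n_ni],
        "n_i": grid.n_i_values[col % n_ni],
    }


def cbdr_params_to_pixel(grid: SweepGrid, f_e, n_e, f_i, n_i) -> tuple[int, int]:
    n_ne, n_ni = len(grid.n_e_values), len(grid.n_i_values)
    return (
        grid.f_e_values.index(f_e) * n_ne + grid.n_e_values.index(n_e),
        grid.f_i_values.index(f_i) * n_ni + grid.n_i_values.index(n_i),
    )


def cbdr_render(
    results: pd.DataFrame,
    grid: SweepGrid,
    png_path=None,
    value: str = "ivl_metric",
) -> np.ndarray:
    """Render the CBDR image (origin lower-left) and its scale-bar sidecar.

    Writes ``png_path`` plus a JSON sidecar (same stem, ``.json``) recording
    the axis nesting so any pixel maps back to its four parameters.
    """
    mat = cbdr_matrix(results, grid, value)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(mat, origin="lower", aspect="auto", cmap="hot",
                       interpolation="nearest")
        ax.set_xlabel("inhibitory: f_I (outer) x N_I (inner)")
        ax.set_ylabel("excitatory: f_E (outer) x N_E (inner)")
        fig.colorbar(im, ax=ax, label=value)
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        sidecar = {
            "value": value,
            "rows": {"outer_f_e": list(grid.f_e_values),
                     "inner_n_e": [int(v) for v in grid.n_e_values]},
            "cols": {"outer_f_i": list(grid.f_i_values),
                     "inner_n_i": [int(v) for v in grid.n_i_values]},
            "origin": "lower",
        }
        with open(str(png_path).rsplit(".", 1)[0] + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
    return mat
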