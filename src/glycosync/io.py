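"""Tabular input/output for cell-trace populations.

Traces travel as long-format TSV (cell_id, t_s, fluorescence) and positions
as one row per cell (cell_id, x_um, y_um[, area_um2]).  Reading validates
the invariants the analysis relies on: a shared uniform time grid, unique
cell ids, and a one-to-one match between the two tables.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import Population

TRACE_COLUMNS = ["cell_id", "t_s", "fluorescence"]
POSITION_COLUMNS = ["cell_id", "x_um", "y_um"]


def write_population(pop: Population, out_dir: str | os.PathLike) -> tuple[str, str]:
    """Write traces.tsv and positions.tsv under ``out_dir``; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    traces_path = os.path.join(out_dir, "traces.tsv")
    positions_path = os.path.join(out_dir, "positions.tsv")

    n, t_len = pop.traces.shape
    long = pd.DataFrame(
        {
            "cell_id": np.repeat(pop.cell_ids, t_len),
            "t_s": np.tile(pop.t, n),
            "fluorescence": pop.traces.ravel(),
        }
    )
    long.to_csv(traces_path, sep="\t", index=False)
    pop.positions.to_csv(positions_path, sep="\t", index=False)
    return traces_path, positions_path


def read_population(path_or_dir: str | os.PathLike, positions_path: str | None = None) -> Population:
    """Read a population written by :func:`write_population`.

    Accepts either a directory containing traces.tsv/positions.tsv or the
    two file paths explicitly.
    """
    if positions_path is None:
        traces_path = os.path.join(path_or_dir, "traces.tsv")
        positions_path = os.path.join(path_or_dir, "positions.tsv")
    else:
        traces_path = str(path_or_dir)

    traces_df = pd.read_csv(traces_path, sep="\t")
    positions = pd.read_csv(positions_path, sep="\t")
    return population_from_tables(traces_df, positions)


def population_from_tables(traces_df: pd.DataFrame, positions: pd.DataFrame) -> Population:
    """Assemble and validate a :class:`Population` from long-format tables."""
    missing = [c for c in TRACE_COLUMNS if c not in traces_df.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    missing = [c for c in POSITION_COLUMNS if c not in positions.columns]
    if missing:
        raise ValueError(f"position table missing columns: {missing}")

    if positions["cell_id"].duplicated().any():
        dup = positions.loc[positions["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicated cell_id in position table: {dup}")

    def _plain(values):
        return sorted(x.item() if hasattr(x, "item") else x for x in values)

    trace_ids = pd.unique(traces_df["cell_id"])
    pos_ids = positions["cell_id"].to_numpy()
    only_traces = _plain(set(trace_ids) - set(pos_ids))
    only_pos = _plain(set(pos_ids) - set(trace_ids))
    if only_traces or only_pos:
        raise ValueError(
            "cell ids do not match between tables: "
            f"only in traces {only_traces[:10]}, only in positions {only_pos[:10]}"
        )
    if len(trace_ids) < 2:
        raise ValueError("population must contain >= 2 cells")

    # all cells must share one uniform time grid
    grids = traces_df.groupby("cell_id", sort=False)["t_s"].apply(tuple)
    ref = grids.iloc[0]
    for cid, grid in grids.items():
        if grid != ref:
            raise ValueError(f"cell {cid!r} is on a different time grid than cell {grids.index[0]!r}")
    t = np.asarray(ref, dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        k = int(np.argmax(dt <= 0))
        raise ValueError(f"time grid not strictly increasing at t={t[k]}..{t[k + 1]}")
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
        k = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6)))
        raise ValueError(f"non-uniform sampling: first offending interval t={t[k]}..{t[k + 1]}")

    # order positions to follow the trace table's cell order
    positions = positions.set_index("cell_id").loc[trace_ids].reset_index()
    mat = np.empty((len(trace_ids), len(t)))
    for i, (cid, grp) in enumerate(traces_df.groupby("cell_id", sort=False)):
        mat[i] = grp["fluorescence"].to_numpy()
    return Population(t=t, traces=mat, positions=positions)


def validate_inputs(traces_path: str, positions_path: str) -> Population:
    """Schema/grid/id cross-check of a trace + position file pair."""
    return read_population(traces_path, positions_path)
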