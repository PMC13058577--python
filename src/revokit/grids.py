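"""Gridded climate containers.

A :class:`ClimateGrid` holds one value per predictor per raster cell for a
single time slice (e.g. the 1970–2000 baseline or a 2061–2080 projection).
Cells are indexed row-major from 0; user-unit coordinates are derived from an
affine transform ``(a, b, c, d, e, f)`` mapping ``(col, row)`` to
``(x, y) = (a*col + b*row + c, d*col + e*row + f)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ClimateGrid", "read_grid_csv", "read_grid_long_csv"]

IDENTITY_AFFINE = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass
class ClimateGrid:
    """Per-cell predictor values for one time slice.

    Parameters
    ----------
    values : pandas.DataFrame
        Index ``cell_id`` (row-major ints), one column per predictor.
    nx, ny : int
        Grid dimensions (columns, rows); ``nx * ny == len(values)``.
    affine : tuple of 6 floats
        Cell-center (col, row) → (x, y) transform.
    label : str
        Time-slice label, e.g. ``"baseline"`` or ``"2061-2080_ssp585"``.
    """

    values: pd.DataFrame
    nx: int
    ny: int
    affine: tuple = field(default=IDENTITY_AFFINE)
    label: str = "baseline"

    def __post_init__(self) -> None:
        if self.nx * self.ny != len(self.values):
            raise ValueError(
                f"grid is {self.nx}x{self.ny} but has {len(self.values)} cells"
            )

    @property
    def predictors(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def coords(self) -> pd.DataFrame:
        """Cell-center coordinates in user units (columns ``x``, ``y``)."""
        cell = self.values.index.to_numpy()
        col = cell % self.nx
        row = cell // self.nx
        a, b, c, d, e, f = self.affine
        return pd.DataFrame(
            {"x": a * col + b * row + c, "y": d * col + e * row + f},
            index=self.values.index,
        )

    def with_label(self, label: str) -> "ClimateGrid":
        return replace(self, label=label)

    def to_csv(self, path) -> None:
        """Write a wide per-cell table (cell, x, y, one column per predictor)."""
        out = pd.concat([self.coords(), self.values], axis=1)
        out.index.name = "cell"
        out.to_csv(path)

    def to_long(self) -> pd.DataFrame:
        """Long format: cell_id, predictor, slice, value."""
        long = self.values.reset_index(names="cell").melt(
            id_vars="cell", var_name="predictor", value_name="value"
        )
        long.insert(2, "slice", self.label)
        return long


def read_grid_csv(path, nx: int, ny: int, affine=IDENTITY_AFFINE,
                  label: str = "baseline") -> ClimateGrid:
    """Read a wide per-cell CSV written by :meth:`ClimateGrid.to_csv`."""
    df = pd.read_csv(path, index_col="cell")
    values = df.drop(columns=[c for c in ("x", "y") if c in df.columns])
    return ClimateGrid(values=values, nx=nx, ny=ny, affine=affine, label=label)


def read_grid_long_csv(path, nx: int, ny: int,
                       affine=IDENTITY_AFFINE) -> list[ClimateGrid]:
    """Read a long-format CSV (cell, predictor, slice, value) into one grid per slice.

    Slice order follows first appearance in the file.
    """
    long = pd.read_csv(path)
    required = {"cell", "predictor", "slice", "value"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"long grid CSV missing columns: {sorted(missing)}")
    grids = []
    for lab in long["slice"].drop_duplicates():
        sub = long[long["slice"] == lab]
        wide = sub.pivot(index="cell", columns="predictor", values="value")
        wide.columns.name = None
        grids.append(ClimateGrid(values=wide, nx=nx, ny=ny, affine=affine,
                                 label=str(lab)))
    return grids
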