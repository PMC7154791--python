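"""Equal-area grid frame, covariate layers and layer stacks.

All spatial data live on a planar equal-area grid of square cells
(default 3 x 3 km).  Latitude and longitude are affine functions of the
row / column index — a flat proxy adequate for median-latitude summaries
on a synthetic ocean, and the frame real Albers-projected rasters are
resampled onto.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

#: units per layer kind
LAYER_UNITS: dict[str, str] = {
    "depth": "m",
    "slope": "degrees",
    "bpi": "dimensionless (z-score)",
    "temp": "degC",
    "epc100": "mg C m-2 day-1",
    "poc_seafloor": "mg C m-2 day-1",
    "co3": "mol/m3",
    "co3_sat_ar": "mol/m3",
    "co3_sat_cal": "mol/m3",
    "omega_ar": "dimensionless",
    "omega_cal": "dimensionless",
    "DO": "umol/kg",
    "pH": "pH units",
    "hsi": "dimensionless",
    "cv": "dimensionless",
}


@dataclass(frozen=True)
class GridSpec:
    """Planar equal-area grid.

    Row 0 is the northern edge; latitude decreases strictly with row
    index.  Longitude increases with column index.  ``cell_size`` is in
    metres.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 3000.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    projection_id: str = "synthetic-equal-area"
    lat_north: float = 76.0
    lat_south: float = 18.0
    lon_west: float = -98.0
    lon_east: float = 36.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8 x 8 cells")
        if self.lat_north == self.lat_south:
            raise ValueError("latitude must vary strictly across rows")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def latitude_of_row(self, row) -> np.ndarray:
        """Affine row -> degrees latitude, strictly monotone."""
        frac = np.asarray(row, dtype=float) / max(self.n_rows - 1, 1)
        return self.lat_north + frac * (self.lat_south - self.lat_north)

    def longitude_of_col(self, col) -> np.ndarray:
        frac = np.asarray(col, dtype=float) / max(self.n_cols - 1, 1)
        return self.lon_west + frac * (self.lon_east - self.lon_west)

    def latitude_grid(self) -> np.ndarray:
        lat = self.latitude_of_row(np.arange(self.n_rows))
        return np.repeat(lat[:, None], self.n_cols, axis=1)

    def xy_of_cell(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates (metres) of cells; y increases northwards."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_of_xy(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`xy_of_cell`; may return out-of-range indices."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        row = self.n_rows - 1 - np.floor(
            (np.asarray(y, float) - self.origin_y) / self.cell_size
        )
        return row.astype(int), col.astype(int)

    def contains_xy(self, x, y) -> np.ndarray:
        row, col = self.cell_of_xy(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_id(self, row, col) -> np.ndarray:
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def rowcol_of_id(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        return cell_id // self.n_cols, cell_id % self.n_cols


@dataclass
class Layer:
    """One covariate field on a grid; NaN marks missing (land) cells."""

    grid: GridSpec
    kind: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer values shape {self.values.shape} != grid {self.grid.shape}"
            )
        if not self.units:
            self.units = LAYER_UNITS.get(self.kind, "")
        if self.kind == "hsi":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("hsi layer must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array: True where the layer is defined."""
        return np.isfinite(self.values)

    def copy(self) -> "Layer":
        return Layer(self.grid, self.kind, self.values.copy(), self.units)

    def at_cells(self, rows, cols) -> np.ndarray:
        return self.values[np.asarray(rows), np.asarray(cols)]


class LayerStack(Mapping[str, Layer]):
    """Grid-aligned collection of layers, keyed by kind."""

    def __init__(self, layers: dict[str, Layer] | None = None):
        self._layers: dict[str, Layer] = {}
        self.grid: GridSpec | None = None
        for layer in (layers or {}).values():
            self.add(layer)

    def add(self, layer: Layer) -> None:
        if self.grid is None:
            self.grid = layer.grid
        elif layer.grid.shape != self.grid.shape:
            raise ValueError("all layers in a stack must share one grid")
        self._layers[layer.kind] = layer

    def __getitem__(self, kind: str) -> Layer:
        return self._layers[kind]

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def copy(self) -> "LayerStack":
        return LayerStack({k: v.copy() for k, v in self._layers.items()})

    @property
    def ocean_mask(self) -> np.ndarray:
        """Cells where every layer is defined."""
        if not self._layers:
            raise ValueError("empty stack has no mask")
        mask = np.ones(self.grid.shape, dtype=bool)
        for layer in self._layers.values():
            mask &= layer.mask
        return mask

    def table_at_cells(self, rows, cols, kinds=None) -> dict[str, np.ndarray]:
        kinds = list(kinds) if kinds is not None else list(self._layers)
        return {k: self._layers[k].at_cells(rows, cols) for k in kinds}
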