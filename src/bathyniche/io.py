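"""Plain-text I/O for layers and occurrence tables.

Layers are written as ESRI ASCII grids (``.asc``) — a single-band text
raster any GIS reads — with the grid's frame in the header and a JSON
sidecar carrying kind, units and the latitude/longitude mapping.
Occurrence tables and training tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, Layer, LayerStack

NODATA = -9999.0

OCCURRENCE_COLUMNS = [
    "species", "x", "y", "lon", "lat",
    "reported_depth_m", "position_accuracy_m", "source",
]


def write_layer(layer: Layer, path: str | Path) -> None:
    path = Path(path)
    g = layer.grid
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x}\n"
        f"yllcorner {g.origin_y}\n"
        f"cellsize {g.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    vals = np.where(layer.mask, layer.values, NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")
    sidecar = {
        "kind": layer.kind,
        "units": layer.units,
        "projection_id": g.projection_id,
        "lat_north": g.lat_north,
        "lat_south": g.lat_south,
        "lon_west": g.lon_west,
        "lon_east": g.lon_east,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_layer(path: str | Path, kind: str | None = None) -> Layer:
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals[vals == header.get("nodata_value", NODATA)] = np.nan
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        projection_id=meta.get("projection_id", "synthetic-equal-area"),
        lat_north=meta.get("lat_north", 76.0),
        lat_south=meta.get("lat_south", 18.0),
        lon_west=meta.get("lon_west", -98.0),
        lon_east=meta.get("lon_east", 36.0),
    )
    return Layer(grid, kind or meta.get("kind", "unknown"), vals, meta.get("units", ""))


def write_stack(stack: LayerStack, directory: str | Path, suffix: str = "") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind, layer in stack.items():
        p = directory / f"{kind}{suffix}.asc"
        write_layer(layer, p)
        paths.append(p)
    return paths


def read_stack(directory: str | Path, suffix: str = "") -> LayerStack:
    directory = Path(directory)
    stack = LayerStack()
    for p in sorted(directory.glob(f"*{suffix}.asc")):
        stack.add(read_layer(p))
    if len(stack) == 0:
        raise FileNotFoundError(f"no .asc layers found in {directory}")
    return stack


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV lacks columns: {missing}")
    return df
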