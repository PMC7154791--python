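"""Occurrence-record quality control and rasterization.

Occurrence tables are pandas DataFrames with columns ``species, x, y,
lon, lat, reported_depth_m, position_accuracy_m, source``.  Filters
partition their input into a kept and a rejected stream; every rejected
record carries a machine-readable ``reject_reason``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, Layer

#: sources whose reported depths are cross-checked against the raster
DEPTH_CHECKED_SOURCES = ("OBIS", "NOAA")
#: source whose positional accuracy is screened
ACCURACY_CHECKED_SOURCE = "ICES_VME"
#: provenance priority for same-cell duplicates (best first)
SOURCE_PRIORITY = ("institutional", "NOAA", "OBIS", "ICES_VME")


@dataclass(frozen=True)
class PresenceCellSet:
    """One presence per occupied grid cell."""

    species: str
    cells: np.ndarray       # sorted unique cell ids
    rows: np.ndarray
    cols: np.ndarray
    sources: np.ndarray     # retained provenance per cell

    @property
    def n_cells(self) -> int:
        return int(self.cells.size)


def _partition(records: pd.DataFrame, reject: np.ndarray, reasons: pd.Series):
    kept = records.loc[~reject].copy()
    rejected = records.loc[reject].copy()
    rejected["reject_reason"] = reasons.loc[reject]
    return kept, rejected


def depth_consistency_filter(
    records: pd.DataFrame,
    depth: Layer,
    rel_tol: float = 0.30,
    abs_tol: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reject records whose reported depth disagrees with the raster.

    Applies to OBIS and NOAA records only (institutional and VME-portal
    depths are taken as reported).  A scoped record is rejected iff its
    depth is missing, or the reported-vs-raster difference exceeds
    *both* ``rel_tol`` of the raster depth *and* ``abs_tol`` metres.
    Records outside the grid extent are rejected regardless of source.
    """
    grid = depth.grid
    inside = grid.contains_xy(records["x"].to_numpy(), records["y"].to_numpy())
    reasons = pd.Series("", index=records.index, dtype=object)
    reject = ~inside
    reasons[~inside] = "out_of_extent"

    scoped = records["source"].isin(DEPTH_CHECKED_SOURCES).to_numpy() & inside
    rows, cols = grid.cell_of_xy(records["x"].to_numpy(), records["y"].to_numpy())
    raster = np.full(len(records), np.nan)
    raster[inside] = depth.values[rows[inside], cols[inside]]
    reported = records["reported_depth_m"].to_numpy(dtype=float)

    missing = scoped & ~np.isfinite(reported)
    diff = np.abs(reported - raster)
    mismatch = scoped & np.isfinite(reported) & (diff > rel_tol * np.abs(raster)) & (diff > abs_tol)
    reasons[missing] = "missing_depth"
    reasons[mismatch] = "depth_mismatch"
    reject |= missing | mismatch
    return _partition(records, reject, reasons)


def position_accuracy_filter(
    records: pd.DataFrame,
    max_error: float = 5000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reject VME-portal records whose positional error exceeds 5 km.

    Only ``ICES_VME`` records are screened; a missing accuracy also
    rejects.  Other sources pass through untouched.
    """
    scoped = (records["source"] == ACCURACY_CHECKED_SOURCE).to_numpy()
    acc = records["position_accuracy_m"].to_numpy(dtype=float)
    missing = scoped & ~np.isfinite(acc)
    coarse = scoped & np.isfinite(acc) & (acc > max_error)
    reasons = pd.Series("", index=records.index, dtype=object)
    reasons[missing] = "missing_position_accuracy"
    reasons[coarse] = "coarse_position"
    return _partition(records, missing | coarse, reasons)


def rasterize_presences(records: pd.DataFrame, grid: GridSpec) -> PresenceCellSet:
    """Collapse QC-passed records to one presence per occupied cell.

    Same-cell duplicates keep the provenance of the highest-priority
    source (institutional > NOAA > OBIS > ICES).
    """
    if len(records) == 0:
        raise ValueError("no surviving records; species cannot be modelled")
    rows, cols = grid.cell_of_xy(records["x"].to_numpy(), records["y"].to_numpy())
    inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    if not inside.all():
        raise ValueError("rasterize_presences received records outside the grid extent")
    cell_ids = grid.cell_id(rows, cols)
    prio = {s: i for i, s in enumerate(SOURCE_PRIORITY)}
    df = pd.DataFrame(
        {
            "cell": cell_ids,
            "source": records["source"].to_numpy(),
            "prio": [prio.get(s, len(prio)) for s in records["source"]],
        }
    )
    best = df.sort_values(["cell", "prio"], kind="stable").drop_duplicates("cell")
    cells = best["cell"].to_numpy()
    r, c = grid.rowcol_of_id(cells)
    species = str(records["species"].iloc[0]) if "species" in records else "unknown"
    return PresenceCellSet(
        species=species,
        cells=cells,
        rows=r,
        cols=c,
        sources=best["source"].to_numpy(),
    )


def run_qc(
    records: pd.DataFrame,
    depth: Layer,
    rel_tol: float = 0.30,
    abs_tol: float = 50.0,
    max_error: float = 5000.0,
) -> tuple[PresenceCellSet, pd.DataFrame, pd.DataFrame]:
    """Full QC chain: depth consistency, positional accuracy, rasterize."""
    kept, rej1 = depth_consistency_filter(records, depth, rel_tol, abs_tol)
    kept, rej2 = position_accuracy_filter(kept, max_error)
    rejected = pd.concat([rej1, rej2], axis=0)
    return rasterize_presences(kept, depth.grid), kept, rejected
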