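"""Binary range maps, present/future change categories and summaries.

HSI maps are thresholded into suitable / unsuitable (``HSI >=
threshold``).  Present and future binary maps combine into loss / gain
/ refugia / never categories (refugia: suitable in both periods), from
which habitat areas, percent change, refugia share and median latitude
/ depth are summarized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, Layer
from .model_eval import ThresholdSpec

#: categorical codes for change maps
CHANGE_CODES = {"never": 0, "loss": 1, "gain": 2, "refugia": 3}


@dataclass(frozen=True)
class BinaryMap:
    grid: GridSpec
    suitable: np.ndarray        # boolean, only meaningful where defined
    defined: np.ndarray         # where the HSI was defined
    threshold: ThresholdSpec
    period: str                 # present | future

    @property
    def n_suitable(self) -> int:
        return int((self.suitable & self.defined).sum())

    @property
    def area_km2(self) -> float:
        return self.n_suitable * self.grid.cell_area_km2


@dataclass(frozen=True)
class ChangeMap:
    grid: GridSpec
    codes: np.ndarray           # CHANGE_CODES values; -1 where undefined
    threshold: ThresholdSpec

    def count(self, category: str) -> int:
        return int((self.codes == CHANGE_CODES[category]).sum())


@dataclass(frozen=True)
class HabitatSummary:
    threshold_rule: str
    area_present_km2: float
    area_future_km2: float
    percent_change: float
    refugia_percent_of_present: float
    median_latitude_present: float
    median_latitude_future: float
    median_depth_present: float
    median_depth_future: float


def binarize(hsi: Layer, threshold: ThresholdSpec, period: str = "present") -> BinaryMap:
    """Suitable iff HSI >= threshold; undefined cells stay undefined."""
    defined = hsi.mask
    suitable = np.zeros(hsi.grid.shape, dtype=bool)
    suitable[defined] = hsi.values[defined] >= threshold.value
    return BinaryMap(hsi.grid, suitable, defined, threshold, period)


def change(present: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Loss / gain / refugia / never partition of the defined cells."""
    if present.grid.shape != future.grid.shape:
        raise ValueError("present and future maps must share one grid")
    if present.threshold.rule != future.threshold.rule:
        raise ValueError(
            f"threshold rules differ: {present.threshold.rule} vs {future.threshold.rule}"
        )
    defined = present.defined & future.defined
    p, f = present.suitable, future.suitable
    codes = np.full(present.grid.shape, -1, dtype=int)
    codes[defined & p & f] = CHANGE_CODES["refugia"]
    codes[defined & p & ~f] = CHANGE_CODES["loss"]
    codes[defined & ~p & f] = CHANGE_CODES["gain"]
    codes[defined & ~p & ~f] = CHANGE_CODES["never"]
    return ChangeMap(present.grid, codes, present.threshold)


def summarize(
    present: BinaryMap,
    future: BinaryMap,
    depth: Layer,
    grid: GridSpec | None = None,
) -> HabitatSummary:
    """Areas (km2), percent change, refugia share and per-period medians."""
    grid = grid or present.grid
    cm = change(present, future)
    a_p = present.area_km2
    a_f = future.area_km2
    if present.n_suitable == 0:
        raise ValueError("present-day suitable set is empty; nothing to summarize")
    a_refugia = cm.count("refugia") * grid.cell_area_km2
    lat = grid.latitude_grid()

    def medians(bmap: BinaryMap) -> tuple[float, float]:
        sel = bmap.suitable & bmap.defined
        if not sel.any():
            return float("nan"), float("nan")
        return float(np.median(lat[sel])), float(np.nanmedian(depth.values[sel]))

    lat_p, dep_p = medians(present)
    lat_f, dep_f = medians(future)
    return HabitatSummary(
        threshold_rule=present.threshold.rule,
        area_present_km2=a_p,
        area_future_km2=a_f,
        percent_change=100.0 * (a_f - a_p) / a_p,
        refugia_percent_of_present=100.0 * a_refugia / a_p,
        median_latitude_present=lat_p,
        median_latitude_future=lat_f,
        median_depth_present=dep_p,
        median_depth_future=dep_f,
    )
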