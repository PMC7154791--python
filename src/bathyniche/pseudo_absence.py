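"""Pseudo-absence (background) generation.

Background cells are drawn inside an environmental profile of the
presence data, outside a 6 km buffer around every presence, and then
depth-stratified so their depth distribution matches the presences.
Group defaults follow the study design: 10,000 background points for
corals, 100,000 for fishes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import GridSpec, LayerStack
from .occurrence_qc import PresenceCellSet

log = logging.getLogger(__name__)

#: group defaults for the number of pseudo-absences
N_PSEUDO_ABSENCE = {"scleractinian": 10_000, "octocoral": 10_000, "fish": 100_000}


@dataclass(frozen=True)
class BackgroundMask:
    grid: GridSpec
    eligible: np.ndarray  # boolean per cell
    bounds: dict  # per-covariate (lo, hi) profile bounds actually used


def env_profile_mask(
    presences: PresenceCellSet,
    stack: LayerStack,
    covariates: list[str] | None = None,
    quantiles: tuple[float, float] = (2.5, 97.5),
    min_coverage: float = 0.95,
    margin: float = 1.0,
) -> BackgroundMask:
    """Environmental profiling: a per-covariate envelope around presences.

    Cells whose covariates fall outside the envelope are ineligible as
    background.  The core box is the ``quantiles`` percentiles of the
    presence covariate values, widened symmetrically until it covers at
    least ``min_coverage`` of the presence cells; each bound is then
    padded outward by ``margin`` times the core box width, the support
    margin a one-class profiling estimator places around its sample.
    The margin keeps clearly-unreachable environments out (a 15 degC
    cell is ineligible when presences sit at 4-6 degC) while leaving
    the background broad enough to span the decline of suitability in
    every direction.  Deterministic in its inputs.
    """
    if presences.n_cells < 20:
        raise ValueError("environmental profiling needs >= 20 presence cells")
    kinds = covariates or [k for k in stack if k not in ("hsi", "cv")]
    pres_vals = {k: stack[k].at_cells(presences.rows, presences.cols) for k in kinds}

    lo_q, hi_q = quantiles
    while True:
        bounds = {
            k: (np.nanpercentile(v, lo_q), np.nanpercentile(v, hi_q))
            for k, v in pres_vals.items()
        }
        covered = np.ones(presences.n_cells, dtype=bool)
        for k, (lo, hi) in bounds.items():
            covered &= (pres_vals[k] >= lo) & (pres_vals[k] <= hi)
        if covered.mean() >= min_coverage or lo_q <= 0:
            break
        lo_q, hi_q = max(lo_q - 0.5, 0.0), min(hi_q + 0.5, 100.0)
    bounds = {
        k: (lo - margin * (hi - lo), hi + margin * (hi - lo))
        for k, (lo, hi) in bounds.items()
    }

    eligible = stack.ocean_mask.copy()
    for k, (lo, hi) in bounds.items():
        v = stack[k].values
        eligible &= np.nan_to_num(v, nan=np.inf) >= lo
        eligible &= np.nan_to_num(v, nan=-np.inf) <= hi
    return BackgroundMask(stack.grid, eligible, bounds)


def sample_background(
    mask: BackgroundMask,
    presences: PresenceCellSet,
    n: int | None,
    buffer_km: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` distinct background cells, none within the presence buffer.

    Distances are planar Euclidean between cell centres on the
    equal-area grid; a cell at exactly the buffer distance is excluded.
    ``n=None`` returns the full post-buffer eligible set.  Returns
    sorted cell ids; reproducible for a given seed.
    """
    grid = mask.grid
    eligible = mask.eligible.copy()
    eligible[presences.rows, presences.cols] = False

    rr, cc = np.nonzero(eligible)
    gx, gy = grid.xy_of_cell(rr, cc)
    px, py = grid.xy_of_cell(presences.rows, presences.cols)
    tree = cKDTree(np.column_stack([px, py]))
    d, _ = tree.query(np.column_stack([gx, gy]), k=1)
    keep = d > buffer_km * 1000.0 + 1e-9
    rr, cc = rr[keep], cc[keep]
    if n is None:
        return np.sort(grid.cell_id(rr, cc))
    if rr.size < n:
        raise ValueError(
            f"only {rr.size} eligible cells after buffering; {n} requested "
            f"(shortfall {n - rr.size})"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(rr.size, size=n, replace=False)
    return np.sort(grid.cell_id(rr[pick], cc[pick]))


def default_strata_edges(depths: np.ndarray, width: float = 250.0) -> np.ndarray:
    """Depth strata: fixed-width bins spanning the occupied depth range."""
    lo = np.floor(np.nanmin(depths) / width) * width
    hi = np.ceil(np.nanmax(depths) / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


def depth_stratified_subsample(
    candidates: np.ndarray,
    candidate_depths: np.ndarray,
    presence_depths: np.ndarray,
    strata_edges: np.ndarray,
    n_target: int,
    seed: int = 0,
) -> np.ndarray:
    """Subsample candidates so their depth strata match the presences.

    Per-stratum counts are ``n_target`` times the presence proportion,
    rounded by the largest-remainder rule so the total is exact;
    within-stratum sampling is uniform without replacement.
    """
    candidates = np.asarray(candidates)
    edges = np.asarray(strata_edges, float)
    p_bin = np.clip(np.digitize(presence_depths, edges) - 1, 0, len(edges) - 2)
    c_bin = np.clip(np.digitize(candidate_depths, edges) - 1, 0, len(edges) - 2)
    n_strata = len(edges) - 1
    prop = np.bincount(p_bin, minlength=n_strata) / len(presence_depths)

    raw = n_target * prop
    counts = np.floor(raw).astype(int)
    rem = n_target - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1

    short = [
        s for s in range(n_strata)
        if counts[s] > 0 and (c_bin == s).sum() < counts[s]
    ]
    if short:
        raise ValueError(
            f"strata {short} have positive targets but too few candidate cells"
        )
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for s in range(n_strata):
        if counts[s] == 0:
            continue
        pool = candidates[c_bin == s]
        chosen.append(rng.choice(pool, size=counts[s], replace=False))
    return np.sort(np.concatenate(chosen))


def assemble_training(
    presences: PresenceCellSet,
    pseudo_absences: np.ndarray,
    stack: LayerStack,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Build the labelled table all model families consume.

    One row per cell with label 1 (presence) or 0 (pseudo-absence),
    covariate values, depth and latitude.  Rows with any missing
    covariate are dropped (count logged).
    """
    pa = np.asarray(pseudo_absences)
    overlap = np.intersect1d(presences.cells, pa)
    if overlap.size:
        raise ValueError(f"{overlap.size} cells appear as both presence and pseudo-absence")
    kinds = covariates or [k for k in stack if k not in ("hsi", "cv")]
    grid = stack.grid

    def block(cells, label):
        r, c = grid.rowcol_of_id(cells)
        data = {"cell_id": cells, "label": label}
        data.update(stack.table_at_cells(r, c, kinds))
        if "depth" not in data:
            data["depth"] = stack["depth"].at_cells(r, c)
        data["latitude"] = grid.latitude_of_row(r)
        return pd.DataFrame(data)

    table = pd.concat(
        [block(presences.cells, 1), block(pa, 0)], axis=0, ignore_index=True
    )
    complete = table[kinds].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        log.warning("dropping %d training rows with missing covariates", n_drop)
    return table.loc[complete].reset_index(drop=True)
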