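"""Seeded synthetic oceans and species occurrences with known niches.

The generator emulates the statistical structure of a basin-scale
seafloor dataset: an equal-area 3 km grid, a bathymetry with shelf /
slope / abyss zones, spatially autocorrelated covariates coupled to
depth (temperature, POC export, carbonate saturation, dissolved
oxygen), a high-emissions future scenario (warming, saturation-horizon
shoaling, POC decline, deoxygenation), and presence records drawn from
a known parametric niche with realistic corruption (missing depths,
depth mismatches, coarse positions).  Every downstream stage of the
pipeline is testable against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import env_layers
from .grid import GridSpec, Layer, LayerStack

#: record sources, in QC priority order
SOURCES = ("institutional", "NOAA", "OBIS", "ICES_VME")


@dataclass(frozen=True)
class NicheResponse:
    covariate: str
    shape: str  # gaussian | increasing-sigmoid | decreasing-sigmoid
    optimum: float  # optimum (gaussian) or inflection (sigmoid), covariate units
    breadth: float  # gaussian sd or sigmoid scale, covariate units

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "increasing-sigmoid", "decreasing-sigmoid"):
            raise ValueError(f"unknown response shape {self.shape!r}")
        if self.breadth <= 0:
            raise ValueError("breadth must be > 0")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, float) - self.optimum) / self.breadth
        if self.shape == "gaussian":
            return np.exp(-0.5 * z**2)
        if self.shape == "increasing-sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        return 1.0 / (1.0 + np.exp(z))


@dataclass(frozen=True)
class NicheSpec:
    """Ground-truth niche: product of unimodal/monotone responses."""

    responses: tuple[NicheResponse, ...]
    max_prevalence: float = 1.0

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("niche needs at least one response")
        if not 0 < self.max_prevalence <= 1:
            raise ValueError("max_prevalence must be in (0, 1]")


@dataclass(frozen=True)
class ScenarioDelta:
    """Per-covariate future transform: x -> factor * x + offset.

    Masked (land) cells are left untouched.  The default emulates an
    end-of-century high-emissions trajectory at the seafloor: bottom
    warming of about 2 degC, a ~45% decline in POC flux (within the
    projected 40%-55% range), saturation-horizon shoaling via a 15%
    carbonate-saturation decline, and a ~4% oxygen loss.
    """

    offsets: dict[str, float] = field(default_factory=dict)
    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, f in self.factors.items():
            if f < 0:
                raise ValueError(f"multiplicative factor for {k} must be >= 0")

    @property
    def covariates(self) -> set[str]:
        return set(self.offsets) | set(self.factors)

    @classmethod
    def rcp85_like(cls) -> "ScenarioDelta":
        return cls(
            offsets={"temp": 2.0, "pH": -0.3},
            factors={
                "epc100": 0.55,
                "poc_seafloor": 0.55,
                "omega_ar": 0.85,
                "omega_cal": 0.85,
                "DO": 0.963,
            },
        )


@dataclass(frozen=True)
class CorruptionSpec:
    """Rates and magnitudes of realistic occurrence-record defects."""

    frac_missing_depth: float = 0.0
    frac_depth_mismatch: float = 0.0
    mismatch_rel: float = 0.5      # relative depth error of a bad record
    mismatch_abs: float = 80.0     # metres added on top, keeps error past both QC tolerances
    frac_coarse_position: float = 0.0
    coarse_accuracy: float = 8000.0  # metres of positional error for coarse records

    def __post_init__(self) -> None:
        for f in (self.frac_missing_depth, self.frac_depth_mismatch, self.frac_coarse_position):
            if not 0 <= f < 1:
                raise ValueError("corruption fractions must be in [0, 1)")
        if self.frac_missing_depth + self.frac_depth_mismatch + self.frac_coarse_position >= 1:
            raise ValueError("corruption fractions must sum to < 1")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated field (filtered white noise)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def build_world(
    grid: GridSpec,
    seed: int,
    land_fraction: float = 0.15,
    smooth_sigma: float | None = None,
    max_depth: float = 4500.0,
) -> tuple[Layer, LayerStack]:
    """Generate a present-day layer stack on the grid.

    The bathymetry spans shelf (< 200 m), slope and abyss (> 2000 m);
    temperature and both saturation states decline with depth, and each
    saturation state crosses 1.0 (its horizon) inside the domain.
    Output is a pure function of ``(grid, seed)``.
    """
    if min(grid.n_rows, grid.n_cols) < 24:
        raise ValueError(
            "grid too small to contain shelf, slope and abyss depth zones; need >= 24 cells per side"
        )
    rng = np.random.default_rng(seed)
    shape = grid.shape
    sigma = smooth_sigma if smooth_sigma is not None else max(min(shape) / 25.0, 2.0)

    # hypsometry: a west-coast gradient plus terrain noise; lowest cells are land
    col_frac = np.tile(np.linspace(0.0, 1.0, grid.n_cols), (grid.n_rows, 1))
    elev_score = col_frac + 0.55 * _smooth_field(rng, shape, sigma)
    land = elev_score < np.quantile(elev_score, land_fraction)
    if (~land).mean() < 0.60:
        raise ValueError("ocean mask below 60% of cells")

    # rank-based hypsometric depth profile: ~20% shelf, mid slope, ~30% abyss
    score = elev_score.copy()
    ocean_scores = score[~land]
    ranks = np.argsort(np.argsort(ocean_scores))
    t = (ranks + 0.5) / ocean_scores.size
    depth_vals = np.full(shape, np.nan)
    depth_vals[~land] = np.maximum(max_depth * t**2.0, 5.0)
    depth_vals[~land] *= 1.0 + 0.04 * _smooth_field(rng, shape, sigma / 2)[~land]
    depth = Layer(grid, "depth", depth_vals)
    z = depth.values
    ocean = depth.mask

    lat = grid.latitude_grid()
    southness = (grid.lat_north - lat) / (grid.lat_north - grid.lat_south)

    def masked(kind, arr):
        arr = np.where(ocean, arr, np.nan)
        return Layer(grid, kind, arr)

    # temperature: warm shallow water, cold abyss, warmer at low latitude;
    # the latitude gradient persists at depth so temperature ranks are not
    # a pure depth proxy (keeps |rho(temp, omega)| below the 0.85 screen
    # while |rho(omega, depth)| stays above it)
    temp = (
        1.5
        + 8.0 * np.exp(-z / 800.0)
        + 5.0 * southness
        + 1.5 * _smooth_field(rng, shape, sigma)
    )

    # export POC flux at 100 m: productive high latitudes, strong mesoscale
    # variability (so seafloor POC is not a pure depth proxy), strictly positive
    epc100 = 20.0 * np.exp(
        0.9 * _smooth_field(rng, shape, sigma) + 0.4 * (1.0 - southness)
    )

    # carbonate system: ion concentration falls with depth, equilibrium
    # concentration rises with pressure, so Omega falls and crosses 1
    co3 = 0.20 - 0.025 * np.log(np.maximum(z, 5.0) / 10.0) + 0.004 * _smooth_field(rng, shape, sigma)
    co3 = np.maximum(co3, 1e-3)
    co3_sat_ar = 0.066 * np.exp(z / 8000.0)
    co3_sat_cal = 0.043 * np.exp(z / 8000.0)

    # dissolved oxygen: mid-depth minimum zone
    do = (
        300.0
        - 90.0 * np.exp(-0.5 * ((z - 900.0) / 500.0) ** 2)
        - 15.0 * southness
        + 8.0 * _smooth_field(rng, shape, sigma)
    )
    ph = 8.1 - 0.25 * (1.0 - np.exp(-z / 1000.0)) + 0.02 * _smooth_field(rng, shape, sigma)

    stack = LayerStack()
    stack.add(depth)
    stack.add(masked("temp", temp))
    stack.add(masked("epc100", epc100))
    stack.add(masked("co3", co3))
    stack.add(masked("co3_sat_ar", co3_sat_ar))
    stack.add(masked("co3_sat_cal", co3_sat_cal))
    stack.add(masked("DO", do))
    stack.add(masked("pH", ph))
    stack.add(env_layers.saturation_state(stack["co3"], stack["co3_sat_ar"], "omega_ar"))
    stack.add(env_layers.saturation_state(stack["co3"], stack["co3_sat_cal"], "omega_cal"))
    stack.add(env_layers.martin_poc(stack["epc100"], depth))
    stack.add(env_layers.slope(depth))
    outer = min(25, min(grid.shape) // 2 - 1)
    stack.add(env_layers.bpi(depth, env_layers.TerrainParams(3, outer)))

    # cells where any derived layer is undefined (e.g. an isolated ocean
    # pocket with an empty BPI annulus) are masked out of every layer so
    # the stack carries one consistent ocean mask
    joint = np.ones(shape, dtype=bool)
    for layer in stack.values():
        joint &= layer.mask
    for layer in stack.values():
        layer.values[~joint] = np.nan
    if joint.mean() < 0.60:
        raise ValueError("ocean mask below 60% of cells")
    for layer in stack.values():
        if not np.all(np.isfinite(layer.values[joint])):
            raise AssertionError(f"non-finite {layer.kind} values on the ocean mask")
    return depth, stack


def apply_scenario(stack: LayerStack, delta: ScenarioDelta) -> LayerStack:
    """Apply per-covariate offsets/factors; untouched covariates are bit-identical."""
    unknown = delta.covariates - set(stack)
    if unknown:
        raise KeyError(f"scenario delta names unknown covariates: {sorted(unknown)}")
    future = stack.copy()
    for kind in delta.covariates:
        layer = future[kind]
        mask = layer.mask
        vals = layer.values
        vals[mask] = vals[mask] * delta.factors.get(kind, 1.0) + delta.offsets.get(kind, 0.0)
    return future


def oracle_suitability(stack: LayerStack, niche: NicheSpec) -> Layer:
    """True suitability: product of niche responses times max prevalence."""
    missing = {r.covariate for r in niche.responses} - set(stack)
    if missing:
        raise KeyError(f"niche covariates not in stack: {sorted(missing)}")
    suit = np.full(stack.grid.shape, niche.max_prevalence)
    for resp in niche.responses:
        suit = suit * resp.evaluate(stack[resp.covariate].values)
    suit[~stack.ocean_mask] = np.nan
    return Layer(stack.grid, "hsi", np.clip(suit, 0.0, 1.0))


def default_coral_niche(stack: LayerStack, strength: float = 1.0) -> NicheSpec:
    """A cold-water-coral-like niche centred on present-day mid-depth conditions.

    Gaussian in temperature around cool slope water, increasing with
    aragonite saturation above its horizon, and increasing with food
    supply — the combination the scenario delta erodes from below.
    ``strength`` > 1 narrows every response (a sharper, easier-to-recover
    niche); < 1 broadens it.
    """
    if strength <= 0:
        raise ValueError("strength must be > 0")
    ocean = stack.ocean_mask
    mid = (stack["depth"].values > 400) & (stack["depth"].values < 1800) & ocean
    t_opt = float(np.nanmedian(stack["temp"].values[mid]))
    poc_med = float(np.nanmedian(stack["poc_seafloor"].values[mid]))
    return NicheSpec(
        responses=(
            NicheResponse("temp", "gaussian", t_opt, 1.6 / strength),
            NicheResponse("omega_ar", "increasing-sigmoid", 1.0, 0.12 / strength),
            NicheResponse(
                "poc_seafloor", "increasing-sigmoid", poc_med * 0.5, poc_med * 0.35 / strength
            ),
        ),
        max_prevalence=0.9,
    )


def simulate_occurrences(
    stack: LayerStack,
    niche: NicheSpec,
    n_target: int,
    corruption: CorruptionSpec | None = None,
    seed: int = 0,
    species: str = "synthetic_species",
) -> pd.DataFrame:
    """Sample presence cells proportionally to the oracle suitability.

    One presence per cell at most (cell-level presence data).  Each
    record carries planar and geographic coordinates, a reported depth,
    a positional accuracy and a source tag; corruption defects are
    applied to disjoint record subsets at exactly the stated rates
    (counts are ``round(frac * n)``).
    """
    corruption = corruption or CorruptionSpec()
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    suit = oracle_suitability(stack, niche).values
    rows, cols = np.nonzero(np.nan_to_num(suit) > 0)
    if rows.size < n_target:
        raise ValueError(
            f"n_target={n_target} exceeds the {rows.size} cells with positive suitability"
        )
    p = suit[rows, cols]

    # Bernoulli acceptance per cell, repeated passes until n_target cells accrue
    chosen: list[int] = []
    remaining = np.arange(rows.size)
    while len(chosen) < n_target:
        order = rng.permutation(remaining)
        accept = order[rng.random(order.size) < p[order]]
        need = n_target - len(chosen)
        chosen.extend(accept[:need].tolist())
        remaining = np.setdiff1d(remaining, accept[:need], assume_unique=False)
        if remaining.size == 0 and len(chosen) < n_target:
            raise ValueError("exhausted suitable cells before reaching n_target")
    idx = np.array(chosen)
    r, c = rows[idx], cols[idx]

    grid = stack.grid
    x, y = grid.xy_of_cell(r, c)
    true_depth = stack["depth"].values[r, c]
    n = n_target
    reported = true_depth.copy()
    accuracy = np.full(n, 100.0)
    source = rng.choice(SOURCES, size=n, p=(0.3, 0.25, 0.35, 0.1)).astype(object)

    n_miss = round(corruption.frac_missing_depth * n)
    n_bad = round(corruption.frac_depth_mismatch * n)
    n_coarse = round(corruption.frac_coarse_position * n)
    perm = rng.permutation(n)
    i_miss = perm[:n_miss]
    i_bad = perm[n_miss:n_miss + n_bad]
    i_coarse = perm[n_miss + n_bad:n_miss + n_bad + n_coarse]

    reported[i_miss] = np.nan
    source[i_miss] = rng.choice(["OBIS", "NOAA"], size=n_miss)
    sign = rng.choice([-1.0, 1.0], size=n_bad)
    reported[i_bad] = np.maximum(
        true_depth[i_bad]
        + sign * (corruption.mismatch_rel * true_depth[i_bad] + corruption.mismatch_abs),
        1.0,
    )
    source[i_bad] = rng.choice(["OBIS", "NOAA"], size=n_bad)
    accuracy[i_coarse] = corruption.coarse_accuracy
    source[i_coarse] = "ICES_VME"

    return pd.DataFrame(
        {
            "species": species,
            "x": x,
            "y": y,
            "lon": grid.longitude_of_col(c),
            "lat": grid.latitude_of_row(r),
            "reported_depth_m": reported,
            "position_accuracy_m": accuracy,
            "source": source,
        }
    )
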