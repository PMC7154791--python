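"""Model-ready predictor layers.

Covers the environmental-layer preparation steps of the pipeline: the
Martin power-law attenuation of POC export flux to the seafloor,
carbonate saturation states, terrain derivatives (Horn slope,
standardized bathymetric position index), coarse-to-fine downscaling
with depth as a drift covariate, and modelled-vs-observed validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal, stats

from .grid import GridSpec, Layer

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MartinParams:
    """Martin-curve parameters: flux(z) = flux(z0) * (z / z0) ** b."""

    export_depth: float = 100.0  # metres; reference depth z0 of the export flux
    exponent: float = -0.858     # canonical open-ocean attenuation exponent

    def __post_init__(self) -> None:
        if self.export_depth <= 0:
            raise ValueError("export_depth must be > 0")


@dataclass(frozen=True)
class TerrainParams:
    """Annulus radii (in cells) for the bathymetric position index."""

    bpi_inner_radius: int = 3
    bpi_outer_radius: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.bpi_inner_radius < self.bpi_outer_radius:
            raise ValueError("require 0 < inner radius < outer radius")


def martin_poc(epc100: Layer, depth: Layer, params: MartinParams | None = None) -> Layer:
    """Attenuate export POC flux from the export depth to the seafloor.

    Per cell: ``poc = epc100 * (depth / export_depth) ** exponent``.
    Cells shallower than the export depth are evaluated by the same
    formula (flux above the export value); no clamping is applied.
    Missing values propagate.
    """
    params = params or MartinParams()
    if epc100.grid.shape != depth.grid.shape:
        raise ValueError("epc100 and depth layers must be grid-aligned")
    both = epc100.mask & depth.mask
    if np.any(depth.values[both] <= 0):
        raise ValueError("depth must be positive (metres below surface) on the mask")
    out = np.full(depth.grid.shape, np.nan)
    z = depth.values[both]
    out[both] = epc100.values[both] * (z / params.export_depth) ** params.exponent
    return Layer(depth.grid, "poc_seafloor", out)


def saturation_state(co3: Layer, co3_eq: Layer, kind: str = "omega_ar") -> Layer:
    """Saturation state: carbonate-ion concentration over its equilibrium value.

    Omega = 1 marks the saturation horizon; Omega < 1 is corrosive to
    the mineral phase the equilibrium concentration refers to.
    """
    if co3.grid.shape != co3_eq.grid.shape:
        raise ValueError("co3 and co3_eq layers must be grid-aligned")
    both = co3.mask & co3_eq.mask
    if np.any(co3_eq.values[both] <= 0):
        raise ValueError("equilibrium carbonate concentration must be > 0 on the mask")
    out = np.full(co3.grid.shape, np.nan)
    out[both] = co3.values[both] / co3_eq.values[both]
    return Layer(co3.grid, kind, out)


def _fill_nearest(values: np.ndarray) -> np.ndarray:
    """Fill NaNs with the nearest finite value (for edge-padding stencils)."""
    mask = np.isfinite(values)
    if mask.all():
        return values
    idx = ndimage.distance_transform_edt(~mask, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def slope(depth: Layer) -> Layer:
    """Terrain slope in degrees from a 3x3 Horn finite-difference stencil."""
    cell = depth.grid.cell_size
    elev = _fill_nearest(-depth.values) if depth.mask.any() else -depth.values
    e = np.pad(elev, 1, mode="edge")
    # Horn 1981 weights
    dzdx = (
        (e[:-2, 2:] + 2 * e[1:-1, 2:] + e[2:, 2:])
        - (e[:-2, :-2] + 2 * e[1:-1, :-2] + e[2:, :-2])
    ) / (8 * cell)
    dzdy = (
        (e[:-2, :-2] + 2 * e[:-2, 1:-1] + e[:-2, 2:])
        - (e[2:, :-2] + 2 * e[2:, 1:-1] + e[2:, 2:])
    ) / (8 * cell)
    deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    deg[~depth.mask] = np.nan
    return Layer(depth.grid, "slope", deg)


def _annulus_kernel(inner: int, outer: int) -> np.ndarray:
    r = np.arange(-outer, outer + 1)
    dist = np.hypot(*np.meshgrid(r, r, indexing="ij"))
    return ((dist >= inner) & (dist <= outer)).astype(float)


def bpi(depth: Layer, params: TerrainParams | None = None) -> Layer:
    """Standardized bathymetric position index.

    Raw BPI is the cell's elevation minus the mean elevation over the
    surrounding annulus (positive = crest, negative = depression); edge
    cells use the truncated annulus.  The output is z-scored over the
    defined cells.
    """
    params = params or TerrainParams()
    if params.bpi_outer_radius >= min(depth.grid.shape) / 2:
        raise ValueError("outer radius must be < min(n_rows, n_cols) / 2")
    kernel = _annulus_kernel(params.bpi_inner_radius, params.bpi_outer_radius)
    elev = -depth.values
    valid = depth.mask.astype(float)
    filled = np.where(depth.mask, elev, 0.0)
    ssum = signal.fftconvolve(filled, kernel, mode="same")
    scount = signal.fftconvolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        annulus_mean = ssum / scount
    raw = elev - annulus_mean
    raw[~depth.mask | (scount < 0.5)] = np.nan
    vals = raw[np.isfinite(raw)]
    sd = vals.std()
    if vals.size < 2 or sd < 1e-12:
        raise ValueError("raw BPI has zero variance; standardization undefined")
    z = (raw - vals.mean()) / sd
    return Layer(depth.grid, "bpi", z)


def _exp_variogram(h, nugget, sill, rng):
    return nugget + sill * (1.0 - np.exp(-h / np.maximum(rng, 1e-9)))


def downscale(
    coarse_x: np.ndarray,
    coarse_y: np.ndarray,
    coarse_values: np.ndarray,
    depth: Layer,
    seed: int = 0,
    nugget: float = 0.0,
) -> Layer:
    """Downscale a coarse point field onto the fine grid.

    Universal-kriging stand-in: a linear drift on depth is regressed
    first, then residuals are interpolated by ordinary kriging with an
    exponential variogram fitted to the empirical semivariance.  With a
    zero nugget the result is an exact interpolator at the coarse sample
    cells.  If the variogram fit fails the residuals fall back to
    inverse-distance weighting (logged).
    """
    x = np.asarray(coarse_x, float)
    y = np.asarray(coarse_y, float)
    v = np.asarray(coarse_values, float)
    if x.size < 10:
        raise ValueError("need at least 10 coarse samples")
    rows, cols = depth.grid.cell_of_xy(x, y)
    if np.any(~depth.grid.contains_xy(x, y)):
        raise ValueError("coarse samples must fall inside the fine grid extent")
    zs = depth.values[rows, cols]
    ok = np.isfinite(zs) & np.isfinite(v)
    x, y, v, zs = x[ok], y[ok], v[ok], zs[ok]

    # drift: v ~ a + b * depth
    X = np.column_stack([np.ones_like(zs), zs])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta

    mask = depth.mask
    rr, cc = np.nonzero(mask)
    gx, gy = depth.grid.xy_of_cell(rr, cc)
    drift = beta[0] + beta[1] * depth.values[rr, cc]

    d_samp = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    interp = _krige_residuals(d_samp, resid, x, y, gx, gy, nugget)
    out = np.full(depth.grid.shape, np.nan)
    out[rr, cc] = drift + interp
    if nugget == 0.0:
        # honour exact interpolation at sample cells even when the fitted
        # variogram is near-degenerate (pure-nugget residual fields leave
        # the kriging system ill-conditioned)
        srows, scols = depth.grid.cell_of_xy(x, y)
        out[srows, scols] = v
    return Layer(depth.grid, "downscaled", out, units="input units")


def _krige_residuals(d_samp, resid, x, y, gx, gy, nugget):
    n = resid.size
    # empirical semivariogram
    iu = np.triu_indices(n, k=1)
    h = d_samp[iu]
    gamma = 0.5 * (resid[iu[0]] - resid[iu[1]]) ** 2
    bins = np.quantile(h, np.linspace(0, 1, 13))
    which = np.clip(np.searchsorted(bins, h, side="right") - 1, 0, 11)
    hb = np.array([h[which == b].mean() if np.any(which == b) else np.nan for b in range(12)])
    gb = np.array([gamma[which == b].mean() if np.any(which == b) else np.nan for b in range(12)])
    good = np.isfinite(hb) & np.isfinite(gb)
    try:
        if good.sum() < 4 or gb[good].max() < 1e-15:
            raise RuntimeError("degenerate empirical variogram")
        p0 = [0.0, max(gb[good].max(), 1e-12), max(hb[good].mean(), 1e-3)]
        popt, _ = optimize.curve_fit(
            _exp_variogram, hb[good], gb[good], p0=p0,
            bounds=([0, 1e-15, 1e-6], [np.inf, np.inf, np.inf]), maxfev=5000,
        )
        fitted_nugget, sill, vrange = popt
    except Exception as err:  # noqa: BLE001 - any fit failure triggers the fallback
        log.warning("variogram fit failed (%s); falling back to IDW residuals", err)
        return _idw(resid, x, y, gx, gy)
    fitted_nugget = nugget if nugget > 0 else 0.0
    # ordinary kriging system with the fitted variogram
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = _exp_variogram(d_samp, fitted_nugget, sill, vrange)
    np.fill_diagonal(K[:n, :n], 0.0)
    K[n, :], K[:, n] = 1.0, 1.0
    K[n, n] = 0.0
    d_tgt = np.hypot(gx[None, :] - x[:, None], gy[None, :] - y[:, None])
    rhs = np.empty((n + 1, gx.size))
    rhs[:n] = _exp_variogram(d_tgt, fitted_nugget, sill, vrange)
    rhs[np.concatenate([d_tgt, np.ones((1, gx.size))]) < 1e-12] = 0.0
    try:
        w = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        log.warning("kriging system singular; falling back to IDW residuals")
        return _idw(resid, x, y, gx, gy)
    return resid @ w[:n]


def _idw(resid, x, y, gx, gy, power: float = 2.0):
    d = np.hypot(gx[None, :] - x[:, None], gy[None, :] - y[:, None])
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[:, exact.any(axis=0)] = exact[:, exact.any(axis=0)].astype(float)
    return (resid @ w) / w.sum(axis=0)


def validate_layer(
    modeled: np.ndarray,
    observed: np.ndarray,
    mode: str = "sqrt_adjusted_r2",
) -> tuple[float, float]:
    """Compare a modelled layer against paired field observations.

    Returns ``(adjusted_R, RMSE)``.  ``adjusted_R`` defaults to the
    square root of the adjusted R-squared of a simple linear fit of
    observed on modelled; ``mode='correlation'`` returns the Pearson
    correlation instead.  RMSE is on the raw modelled-observed
    differences.
    """
    m = np.asarray(modeled, float)
    o = np.asarray(observed, float)
    if m.size != o.size or m.size < 3:
        raise ValueError("need >= 3 paired points")
    if m.std() < 1e-15 or o.std() < 1e-15:
        raise ValueError("zero variance in modelled or observed values")
    r = stats.pearsonr(m, o).statistic
    n = m.size
    if mode == "correlation":
        adj_r = r
    elif mode == "sqrt_adjusted_r2":
        adj_r2 = 1.0 - (1.0 - r**2) * (n - 1) / (n - 2)
        adj_r = float(np.sqrt(max(adj_r2, 0.0)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rmse = float(np.sqrt(np.mean((o - m) ** 2)))
    return float(adj_r), rmse
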