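"""Bare-ground DEM construction, crop surface models, vegetation segmentation.

The digital elevation model (DEM) is interpolated by ordinary kriging from
elevation points sampled on bare soil, driven by a variogram fitted to those
points.  Subtracting the DEM from each flight's digital surface model (DSM)
yields the crop surface model (CSM), a per-cell canopy height.  Vegetation is
separated from soil with the excess-green index computed on chromatic
coordinates, thresholded by Otsu's method by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from skimage.filters import threshold_otsu

from .raster import Raster

logger = logging.getLogger(__name__)

__all__ = [
    "VariogramModel",
    "fit_variogram",
    "krige_points",
    "krige_dem",
    "compute_csm",
    "excess_green",
    "vegetation_mask",
]

_FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram gamma(h) with a nugget, sill and range.

    ``sill`` is the total sill (nugget + partial sill); ``range_`` is the
    distance scale in world units.  ``degenerate`` flags a nugget-only model
    fitted to a zero-variance point set.
    """

    family: str
    nugget: float
    sill: float
    range_: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.sill < self.nugget:
            raise ValueError("sill must be >= nugget")
        if self.range_ <= 0:
            raise ValueError("range must be > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        gamma = np.where(h > 0, self.nugget, 0.0)
        if self.family == "exponential":
            struct = 1.0 - np.exp(-3.0 * h / self.range_)
        elif self.family == "gaussian":
            struct = 1.0 - np.exp(-3.0 * (h / self.range_) ** 2)
        else:  # spherical
            hr = np.minimum(h / self.range_, 1.0)
            struct = 1.5 * hr - 0.5 * hr**3
        return gamma + psill * struct


def _structural(family: str):
    if family == "exponential":
        return lambda h, r: 1.0 - np.exp(-3.0 * h / r)
    if family == "gaussian":
        return lambda h, r: 1.0 - np.exp(-3.0 * (h / r) ** 2)

    def spherical(h, r):
        hr = np.minimum(h / r, 1.0)
        return 1.5 * hr - 0.5 * hr**3

    return spherical


def fit_variogram(
    points: np.ndarray,
    family: str = "exponential",
    n_lags: int = 15,
) -> VariogramModel:
    """Fit a variogram model to bare-ground points by binned least squares.

    Parameters
    ----------
    points
        ``(n, 3)`` array of (x, y, elevation) records.
    family
        Model family: exponential (default), spherical or gaussian.
    n_lags
        Number of distance classes for the empirical semivariogram
        (equal-width bins up to half the maximum pairwise distance).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (x, y, z)")
    n = len(points)
    if n < 10:
        raise ValueError(f"need at least 10 points to fit a variogram, got {n}")
    if n_lags < 2:
        raise ValueError("n_lags must be >= 2")
    if family not in _FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")

    z = points[:, 2]
    if np.ptp(z) == 0.0:
        logger.warning("all elevations identical; returning nugget-only variogram")
        return VariogramModel(family, 0.0, 0.0, 1.0, degenerate=True)

    d = pdist(points[:, :2])
    dz2 = pdist(z[:, None], metric="sqeuclidean")  # (z_i - z_j)^2
    dmax = d.max() / 2.0
    edges = np.linspace(0.0, dmax, n_lags + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= dmax
    counts = np.bincount(which[keep], minlength=n_lags)
    sums = np.bincount(which[keep], weights=dz2[keep], minlength=n_lags)
    nonempty = counts > 0
    lag_centers = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    gamma_emp = 0.5 * sums[nonempty] / counts[nonempty]
    if nonempty.sum() < 3:
        raise ValueError("too few populated lag classes to fit a variogram")

    struct = _structural(family)

    def model(h, nugget, psill, rng):
        return nugget + psill * struct(h, rng)

    var_z = float(np.var(z))
    p0 = [0.0, var_z, dmax / 2.0]
    bounds = ([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf])
    popt, _ = curve_fit(
        model, lag_centers, gamma_emp, p0=p0, bounds=bounds, maxfev=20000
    )
    nugget, psill, rng = (float(v) for v in popt)
    return VariogramModel(family, nugget, nugget + psill, rng)


def _solve_ok(coords: np.ndarray, z: np.ndarray, variogram: VariogramModel,
              targets: np.ndarray) -> np.ndarray:
    """Dense ordinary-kriging solve: all points used for every target."""
    n = len(coords)
    gamma_pp = variogram(squareform(pdist(coords)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_pp
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    d = np.linalg.norm(targets[:, None, :] - coords[None, :, :], axis=2)
    rhs = np.empty((len(targets), n + 1))
    rhs[:, :n] = variogram(d)
    rhs[:, n] = 1.0
    try:
        sol = np.linalg.solve(a, rhs.T)
    except np.linalg.LinAlgError:
        logger.warning("singular kriging system; returning NaN predictions")
        return np.full(len(targets), np.nan)
    return sol[:n].T @ z


def krige_points(
    points: np.ndarray,
    variogram: VariogramModel,
    targets: np.ndarray,
    max_neighbors: int = 16,
    chunk: int = 20000,
) -> np.ndarray:
    """Ordinary-kriging prediction at arbitrary target locations.

    Each target uses its ``max_neighbors`` nearest data points (the full set
    when ``n <= max_neighbors``).  Kriging weights sum to one by construction;
    with a zero nugget the predictor interpolates the data exactly.  Targets
    whose local system is singular come back as NaN.
    """
    points = np.asarray(points, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if len(points) < 3:
        raise ValueError("kriging needs at least 3 points")
    coords, z = points[:, :2], points[:, 2]
    n = len(coords)
    if variogram.degenerate or variogram.sill == 0.0:
        # Zero-variance field: every weight vector averaging the (identical)
        # data reproduces the constant surface.
        return np.full(len(targets), float(z.mean()))
    if n <= max_neighbors:
        return _solve_ok(coords, z, variogram, targets)

    k = max_neighbors
    tree = cKDTree(coords)
    out = np.empty(len(targets))
    for lo in range(0, len(targets), chunk):
        t = targets[lo : lo + chunk]
        dist, idx = tree.query(t, k=k)
        nb = coords[idx]  # (m, k, 2)
        pair = np.linalg.norm(nb[:, :, None, :] - nb[:, None, :, :], axis=3)
        a = np.empty((len(t), k + 1, k + 1))
        a[:, :k, :k] = variogram(pair)
        a[:, k, :] = 1.0
        a[:, :, k] = 1.0
        a[:, k, k] = 0.0
        rhs = np.empty((len(t), k + 1))
        rhs[:, :k] = variogram(dist)
        rhs[:, k] = 1.0
        try:
            sol = np.linalg.solve(a, rhs[:, :, None])[:, :k, 0]
            pred = np.einsum("mk,mk->m", sol, z[idx])
        except np.linalg.LinAlgError:
            # Fall back to per-target solves so one degenerate neighborhood
            # does not poison the chunk.
            pred = np.empty(len(t))
            for i in range(len(t)):
                try:
                    w = np.linalg.solve(a[i], rhs[i])[:k]
                    pred[i] = w @ z[idx[i]]
                except np.linalg.LinAlgError:
                    logger.warning("singular kriging neighborhood at target %d", lo + i)
                    pred[i] = np.nan
        out[lo : lo + chunk] = pred
    return out


def krige_dem(
    points: np.ndarray,
    variogram: VariogramModel,
    target_grid: Raster,
    max_neighbors: int = 16,
) -> Raster:
    """Interpolate a DEM over ``target_grid``'s cells by ordinary kriging."""
    xs, ys = target_grid.cell_centers()
    targets = np.column_stack([xs.ravel(), ys.ravel()])
    pred = krige_points(points, variogram, targets, max_neighbors=max_neighbors)
    values = pred.reshape(target_grid.shape)
    bad = np.isnan(values)
    if bad.any():
        logger.warning("%d DEM cells unsolvable; set to nodata", int(bad.sum()))
        values = np.where(bad, target_grid.nodata, values)
    return target_grid.copy_with(values)


def compute_csm(dsm: Raster, dem: Raster, smooth_window: int | None = None) -> Raster:
    """Crop surface model: cellwise DSM - DEM, negatives clamped to zero.

    Heights below ground are interpolation noise, so negative differences are
    clamped to 0 and the clamped-cell count logged.  Nodata in either input
    propagates to the output.  ``smooth_window`` (odd, off by default)
    applies a window-mean smoothing of the difference surface before
    clamping, for workflows that re-smooth the canopy surface prior to
    extraction.
    """
    if not dsm.same_grid(dem):
        raise ValueError("DSM and DEM grids differ (shape or transform)")
    valid = dsm.mask_valid() & dem.mask_valid()
    diff = dsm.values - dem.values
    if smooth_window is not None:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")
        from scipy.ndimage import uniform_filter
        num = uniform_filter(np.where(valid, diff, 0.0), size=smooth_window,
                             mode="reflect")
        den = uniform_filter(valid.astype(float), size=smooth_window,
                             mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = np.where(den > 0, num / den, 0.0)
    n_clamped = int(np.sum((diff < 0) & valid))
    if n_clamped:
        logger.warning("CSM: clamped %d negative cells to 0", n_clamped)
    csm = np.where(valid, np.maximum(diff, 0.0), dsm.nodata)
    return dsm.copy_with(csm)


def excess_green(rgb: Raster) -> Raster:
    """Excess-green index ExG = 2g - r - b on chromatic coordinates.

    r, g, b are channel intensities normalized by R+G+B, which makes the
    index invariant to uniform illumination scaling.  Pixels with
    R+G+B = 0 (and nodata pixels) map to nodata.  Output range is [-1, 2].
    """
    if rgb.n_bands != 3:
        raise ValueError(f"excess_green expects a 3-band raster, got {rgb.n_bands}")
    if np.any((rgb.values < 0) & (rgb.values != rgb.nodata)):
        raise ValueError("negative channel intensities")
    red, grn, blu = rgb.values
    total = red + grn + blu
    valid = rgb.mask_valid() & (total > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = (2.0 * grn - red - blu) / total
    out = np.where(valid, exg, rgb.nodata)
    return Raster(out, rgb.transform, nodata=rgb.nodata, units="index")


def vegetation_mask(
    exg: Raster, method: str = "otsu", threshold: float | None = None
) -> Raster:
    """Binary vegetation mask: 1 where ExG exceeds the threshold.

    ``method='otsu'`` computes the threshold from the valid-pixel histogram;
    ``method='fixed'`` uses the supplied value.  Nodata is preserved.
    """
    if exg.values.ndim != 2:
        raise ValueError("vegetation_mask expects a single-band index raster")
    valid = exg.mask_valid()
    if method == "otsu":
        vals = exg.values[valid]
        if vals.size == 0:
            raise ValueError("no valid pixels to threshold")
        thr = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else float(vals[0])
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown mask method {method!r}")
    mask = np.where(valid, (exg.values > thr).astype(float), exg.nodata)
    out = exg.copy_with(mask)
    out.units = "binary"
    out.threshold = thr  # kept for inspection/reporting
    return out
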