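"""Per-plot plant-height extraction from the CSM and ruler validation.

One height per plot per flight is read from the crop surface model restricted
to vegetation pixels inside the plot polygon.  The default reducer is the
"maximum adjacent pixel" statistic: the largest window-mean of the CSM over
the masked pixels, which estimates the tallest plant while damping single-
pixel spikes.  UAV heights are validated against ruler measurements by
ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter
from scipy.stats import linregress
from shapely import wkt as shapely_wkt
from shapely.geometry.base import BaseGeometry

from .raster import Raster

logger = logging.getLogger(__name__)

__all__ = [
    "PlotMap",
    "ValidationResult",
    "extract_plot_height",
    "extract_all",
    "aggregate_to_lines",
    "validate_heights",
]


@dataclass
class PlotMap:
    """Per-plot polygons (world coordinates) with line IDs and group labels."""

    table: pd.DataFrame  # plot_id, line_id, group, geometry (shapely)

    REQUIRED = ("plot_id", "line_id", "group", "geometry")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"plot map missing columns: {missing}")
        geoms = self.table["geometry"]
        if not all(isinstance(g, BaseGeometry) and g.is_valid for g in geoms):
            raise ValueError("plot polygons must be valid shapely geometries")
        tree = shapely.STRtree(list(geoms))
        left, right = tree.query(list(geoms), predicate="intersects")
        overlap = [
            (i, j) for i, j in zip(left, right)
            if i < j and geoms.iloc[i].intersection(geoms.iloc[j]).area > 0
        ]
        if overlap:
            raise ValueError(f"plot polygons overlap: pairs {overlap[:5]}")
        if self.table[["plot_id", "line_id", "group"]].isna().any().any():
            raise ValueError("every plot needs plot_id, line_id and group")

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["geometry"] = [g.wkt for g in out["geometry"]]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlotMap":
        table = pd.read_csv(path)
        table["geometry"] = [shapely_wkt.loads(w) for w in table["geometry"]]
        return cls(table)


@dataclass(frozen=True)
class ValidationResult:
    """OLS fit of ruler heights on UAV heights plus the Pearson correlation."""

    slope: float
    intercept: float
    r: float
    r2: float
    n: int


def _neighborhood_mean(csm: Raster, window: int) -> np.ndarray:
    """window x window mean of the CSM, nodata-aware (reflect at edges)."""
    valid = csm.mask_valid()
    vals = np.where(valid, csm.values, 0.0)
    num = uniform_filter(vals, size=window, mode="reflect")
    den = uniform_filter(valid.astype(float), size=window, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / den
    return np.where(den > 0, mean, np.nan)


def _in_polygon_pixels(raster: Raster, polygon) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of cells whose centres lie inside the polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    t = raster.transform
    r0, c0 = t.index(minx, maxy)
    r1, c1 = t.index(maxx, miny)
    nrow, ncol = raster.shape
    r0, r1 = max(0, min(r0, r1) - 1), min(nrow - 1, max(r0, r1) + 1)
    c0, c1 = max(0, min(c0, c1) - 1), min(ncol - 1, max(c0, c1) + 1)
    if r0 > r1 or c0 > c1:
        return np.empty(0, int), np.empty(0, int)
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                             indexing="ij")
    xs, ys = t.xy(rows, cols)
    inside = shapely.contains_xy(polygon, xs.ravel(), ys.ravel())
    return rows.ravel()[inside], cols.ravel()[inside]


def extract_plot_height(
    csm: Raster,
    mask: Raster,
    plot,
    method: str = "max_adjacent",
    window: int = 3,
    p: float = 99.0,
    _smoothed: np.ndarray | None = None,
) -> float:
    """Extract one plant height (cm) for a plot polygon.

    ``max_adjacent`` returns the maximum, over masked vegetation pixels
    inside the polygon, of the window x window neighborhood mean of the CSM;
    ``percentile`` returns the ``p``-th percentile of masked in-polygon CSM
    values.  Returns NaN when no vegetation pixel falls inside the polygon.
    """
    if not csm.same_grid(mask):
        raise ValueError("CSM and mask grids differ")
    if method == "max_adjacent" and window % 2 == 0:
        raise ValueError("window must be odd")
    if method not in ("max_adjacent", "percentile"):
        raise ValueError(f"unknown method {method!r}")
    rows, cols = _in_polygon_pixels(csm, plot)
    if rows.size == 0:
        logger.warning("plot polygon contains no raster cells")
        return float("nan")
    veg = (mask.values[rows, cols] == 1) & (csm.values[rows, cols] != csm.nodata)
    if not veg.any():
        logger.warning("no vegetation pixel inside plot polygon")
        return float("nan")
    rows, cols = rows[veg], cols[veg]
    if method == "percentile":
        return float(np.percentile(csm.values[rows, cols], p))
    smoothed = _smoothed if _smoothed is not None else _neighborhood_mean(csm, window)
    return float(np.nanmax(smoothed[rows, cols]))


def extract_all(
    csm: Raster,
    mask: Raster,
    plots: PlotMap,
    method: str = "max_adjacent",
    window: int = 3,
    p: float = 99.0,
) -> pd.DataFrame:
    """Extract heights for every plot; one record per plot.

    Plots without vegetation pixels (or outside the raster) are returned
    with NaN height and logged, never fatal.
    """
    smoothed = _neighborhood_mean(csm, window) if method == "max_adjacent" else None
    records = []
    for _, row in plots.table.iterrows():
        h = extract_plot_height(csm, mask, row["geometry"], method=method,
                                window=window, p=p, _smoothed=smoothed)
        records.append({"plot_id": row["plot_id"], "line_id": row["line_id"],
                        "group": row["group"], "height_cm": h, "method": method})
    out = pd.DataFrame(records)
    n_missing = int(out["height_cm"].isna().sum())
    if n_missing:
        logger.warning("%d plot(s) yielded no height and were excluded "
                       "from aggregation", n_missing)
    return out


def aggregate_to_lines(per_plot: pd.DataFrame) -> pd.DataFrame:
    """Line-level heights: mean over a line's plots, missing plots excluded."""
    ok = per_plot.dropna(subset=["height_cm"])
    agg = (ok.groupby(["line_id", "group"], as_index=False)["height_cm"].mean())
    return agg.sort_values("line_id", kind="mergesort").reset_index(drop=True)


def validate_heights(ph_uav, ph_ruler) -> ValidationResult:
    """OLS regression of ruler heights on UAV heights (PH_R ~ PH_UAV).

    Inputs may be pandas Series indexed by plot_id (paired on the index) or
    plain aligned arrays.  Pooling across stages is done by concatenating the
    stage pairs before calling this function.
    """
    if isinstance(ph_uav, pd.Series) and isinstance(ph_ruler, pd.Series):
        joined = pd.concat([ph_uav.rename("uav"), ph_ruler.rename("ruler")],
                           axis=1, join="inner").dropna()
        x, y = joined["uav"].to_numpy(), joined["ruler"].to_numpy()
    else:
        x = np.asarray(ph_uav, dtype=float)
        y = np.asarray(ph_ruler, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired plots")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in heights")
    fit = linregress(x, y)
    return ValidationResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue), float(fit.rvalue**2), len(x))
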