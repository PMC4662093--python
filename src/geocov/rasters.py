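"""Point extraction and summaries from raster stacks.

Covers the band-ratio vegetation index, cell-value extraction without
interpolation, annual composite-stack summaries, the pooled August
median, and the concentric-ring relative-elevation metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from geocov.errors import GeocovError
from geocov.model import MonitoringSite, NdviStack, RasterGrid

logger = logging.getLogger(__name__)


def ndvi_from_bands(nir: float, red: float) -> float:
    """(NIR − RED) / (NIR + RED), in [−1, 1]; NaN when NIR + RED = 0.

    Works elementwise on arrays as well as scalars.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0.0, (nir - red) / denom, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def extract_cell_value(site: MonitoringSite, raster: RasterGrid) -> float:
    """Value of the cell whose half-open footprint contains the site.

    No interpolation: a site on a shared edge reads the +x/+y cell.
    Returns NaN (missing) outside the extent or on a nodata cell.
    """
    idx = raster.cell_index(site.x, site.y)
    if idx is None:
        logger.warning("site %s outside raster extent %s", site.site_id, raster.extent)
        return math.nan
    v = float(raster.values[idx])
    if raster.is_nodata(v):
        return math.nan
    return v


@dataclass(frozen=True)
class NdviSummary:
    site_id: str
    annual_mean: float
    annual_min: float
    annual_max: float
    august_median: float = math.nan


def ndvi_stack_summary(site: MonitoringSite, stack: NdviStack) -> NdviSummary:
    """Mean/min/max of the site's cell value across a year's composites,
    ignoring nodata; all-nodata yields a missing (NaN) summary."""
    values = []
    for _date, grid in stack:
        v = extract_cell_value(site, grid)
        if not math.isnan(v):
            values.append(v)
    if not values:
        logger.warning("site %s: no valid composite values", site.site_id)
        return NdviSummary(site.site_id, math.nan, math.nan, math.nan)
    arr = np.array(values)
    return NdviSummary(
        site.site_id,
        annual_mean=float(arr.mean()),
        annual_min=float(arr.min()),
        annual_max=float(arr.max()),
    )


def _default_august(d) -> bool:
    return d.month == 8


def ndvi_august_median(
    site: MonitoringSite,
    stacks_by_year: Iterable[NdviStack],
    august_selector: Callable = _default_august,
) -> float:
    """Median of the site's August composite values pooled over the
    supplied years (previous/current/following). Even counts take the
    mean of the central pair. NaN when no August composite exists."""
    pooled = []
    for stack in stacks_by_year:
        for d, grid in stack:
            if august_selector(d):
                v = extract_cell_value(site, grid)
                if not math.isnan(v):
                    pooled.append(v)
    if not pooled:
        logger.warning("site %s: no August composites", site.site_id)
        return math.nan
    return float(np.median(pooled))


@dataclass(frozen=True)
class RelativeElevation:
    site_id: str
    ring_radius: float
    threshold: float
    direction: str  # above | below
    proportion: float  # percent in [0, 100]


def relative_elevation(
    site: MonitoringSite,
    dem: RasterGrid,
    ring_radius: float,
    threshold: float,
    direction: str,
    ring_width: float = 30.0,
) -> RelativeElevation:
    """Percent of ring cells whose elevation differs from the site's by
    more than a threshold.

    The ring is a centered annulus of total width ``ring_width`` (radii
    ``ring_radius ± ring_width/2``); a DEM cell belongs to the ring iff
    its center falls in the annulus (the common zonal convention; the
    alternative any-overlap rule is deliberately not used so counts are
    unambiguous). With e0 the site's cell elevation, direction ``above``
    counts cells with elevation > e0 + threshold and ``below`` counts
    cells with elevation < e0 − threshold; the proportion is 100 ×
    count / (valid ring cells). Thresholds are absolute differences from
    the site, not absolute elevations.
    """
    if direction not in ("above", "below"):
        raise GeocovError(f"direction must be 'above' or 'below', got {direction!r}")
    if ring_radius <= 0 or ring_width <= 0:
        raise GeocovError("ring_radius and ring_width must be > 0")
    e0 = extract_cell_value(site, dem)
    if math.isnan(e0):
        return RelativeElevation(site.site_id, ring_radius, threshold, direction, math.nan)

    r_in = ring_radius - ring_width / 2.0
    r_out = ring_radius + ring_width / 2.0
    xmin, ymin, xmax, ymax = dem.extent
    if (
        site.x - r_out < xmin
        or site.x + r_out > xmax
        or site.y - r_out < ymin
        or site.y + r_out > ymax
    ):
        logger.warning(
            "site %s: %.0f m ring extends beyond DEM extent; using partial ring",
            site.site_id, ring_radius,
        )

    xs, ys = dem.cell_centers()
    dx = xs - site.x
    dy = ys - site.y
    dist2 = dy[:, None] ** 2 + dx[None, :] ** 2
    in_ring = (dist2 >= r_in**2) & (dist2 <= r_out**2)
    ring_vals = dem.values[in_ring]
    valid = ring_vals[~(np.isnan(ring_vals) | (ring_vals == dem.nodata))]
    if valid.size == 0:
        logger.warning("site %s: no DEM cells on the %.0f m ring", site.site_id, ring_radius)
        return RelativeElevation(site.site_id, ring_radius, threshold, direction, math.nan)
    if direction == "above":
        count = int(np.sum(valid > e0 + threshold))
    else:
        count = int(np.sum(valid < e0 - threshold))
    return RelativeElevation(
        site.site_id,
        ring_radius,
        threshold,
        direction,
        100.0 * count / valid.size,
    )
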