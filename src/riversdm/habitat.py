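"""Thresholding suitability maps into suitable-habitat masks and polygons.

The threshold is the mean predicted probability at the presence cells of
the averaged suitability map ("average predicted probability"), and
"above the threshold" is implemented inclusively (p ≥ t) so that the
threshold-defining average case itself counts as suitable.  Suitable
cells are grouped into 4-connected regions and traced as lon/lat
polygons whose vertices lie on cell edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union
from shapely import STRtree
import shapely.geometry as sgeom

from .grid import GridGeometry, Raster
from .maxent import SuitabilityMap

__all__ = ["HabitatMask", "mean_presence_threshold", "binarize",
           "polygonize", "rasterize_polygons"]

#: 4-connectivity structuring element (no diagonals)
_STRUCTURE4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def mean_presence_threshold(suitability: SuitabilityMap,
                            presences: np.ndarray,
                            mode: str = "presence") -> float:
    """Threshold t for reclassification.

    ``mode="presence"`` (default): arithmetic mean of p at the presence
    cells — the mean-presence-probability rule.  ``mode="map"``: mean of
    p over all valid cells, available as the alternative reading of
    "average predicted probability".
    """
    data = suitability.data
    if mode == "map":
        return float(np.nanmean(data))
    presences = np.asarray(presences, dtype=int)
    if len(presences) == 0:
        raise ValueError("presence set is empty")
    vals = data[presences[:, 0], presences[:, 1]]
    if np.any(np.isnan(vals)):
        raise ValueError("some presences fall on nodata cells")
    return float(np.mean(vals))


@dataclass
class HabitatMask:
    """Binary suitable/unsuitable grid plus its polygon representation."""

    threshold: float
    grid: np.ndarray                    # 1 suitable, 0 unsuitable, NaN nodata
    geometry: GridGeometry
    polygons: list = field(default_factory=list)

    @property
    def suitable_count(self) -> int:
        return int(np.nansum(self.grid))

    def polygon_union(self):
        return unary_union(self.polygons) if self.polygons else \
            sgeom.MultiPolygon([])


def binarize(suitability: SuitabilityMap, t: float) -> HabitatMask:
    """Cell suitable iff p ≥ t; nodata stays nodata."""
    if not (0.0 < t < 1.0):
        raise ValueError(f"threshold {t} outside (0, 1)")
    data = suitability.data
    grid = np.where(np.isnan(data), np.nan, (data >= t).astype(float))
    return HabitatMask(t, grid, suitability.geometry)


def polygonize(mask: HabitatMask) -> HabitatMask:
    """Trace 4-connected suitable regions as lon/lat polygons.

    Each region becomes one polygon (with holes where it surrounds
    unsuitable cells); vertices lie on cell edges.  An empty mask yields
    an empty polygon list.  Returns the mask with ``polygons`` filled.
    """
    suitable = np.nan_to_num(mask.grid, nan=0.0) >= 1.0
    labels, n = ndimage.label(suitable, structure=_STRUCTURE4)
    g = mask.geometry
    polys = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        boxes = [box(g.west + c * g.cellsize, g.north - (r + 1) * g.cellsize,
                     g.west + (c + 1) * g.cellsize, g.north - r * g.cellsize)
                 for r, c in zip(rows, cols)]
        merged = unary_union(boxes)
        polys.append(merged)
    mask.polygons = polys
    return mask


def rasterize_polygons(polygons, geometry: GridGeometry) -> np.ndarray:
    """Point-in-polygon at cell centers: the inverse of polygonize.

    Cell centers on a polygon boundary count as inside (closed regions).
    """
    out = np.zeros(geometry.shape, dtype=float)
    if not polygons:
        return out
    union = unary_union(polygons)
    lon, lat = geometry.cell_centers()
    pts = [sgeom.Point(x, y) for x, y in zip(lon.ravel(), lat.ravel())]
    tree = STRtree(pts)
    idx = tree.query(union, predicate="intersects")
    flat = out.ravel()
    flat[np.asarray(idx, dtype=int)] = 1.0
    return flat.reshape(geometry.shape)
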