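"""Regions of interest, vessel point patterns and point-to-ROI distance histograms.

All geometry is planar and carried in millimetres.  An :class:`RoiSet` holds up
to three labeled regions of a slide — the tumor itself, the intestinal lumen
and the adjacent (host) tissue — each as one or more simple polygons, possibly
with holes.  Distances from vessel centroids to a reference region are the raw
material of the belt-zone statistic: the distance is zero for a point inside
the region and the shortest Euclidean distance to the region boundary
otherwise.

The distance kernel is a vectorized minimum over boundary segments (with a
closed form for axis-aligned rectangles); the Monte-Carlo null evaluates it
~10^8 times per cohort, so it avoids per-point geometry objects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, shape as shapely_shape, mapping as shapely_mapping

from .errors import DegenerateInputError, GeometryError, LabelError

__all__ = [
    "TUMOR",
    "LUMEN",
    "ADJACENT",
    "canonical_label",
    "PointPattern",
    "RoiSet",
    "DistanceDistribution",
    "distance_to_roi",
    "distances_to_roi",
    "distance_distribution",
]

TUMOR = "tumor"
LUMEN = "lumen"
ADJACENT = "adjacent"

_ALIASES = {
    "tumor": TUMOR,
    "tumour": TUMOR,
    "lumen": LUMEN,
    "intestinallumen": LUMEN,
    "intestinal lumen": LUMEN,
    "intestinal_lumen": LUMEN,
    "adjacent": ADJACENT,
    "adjacenttissue": ADJACENT,
    "adjacent tissue": ADJACENT,
    "adjacent_tissue": ADJACENT,
}


def canonical_label(label: str) -> str:
    """Map the accepted spellings (``Tumor``, ``IntestinalLumen``, ...) onto
    the canonical lowercase labels used throughout the package."""
    key = label.strip().lower()
    if key not in _ALIASES:
        raise LabelError(f"unknown ROI label {label!r}; expected one of tumor/lumen/adjacent")
    return _ALIASES[key]


@dataclass
class PointPattern:
    """Planar vessel centroids (mm) inside a named region.

    Attributes
    ----------
    points : (N, 2) float array of (x, y) positions in mm.
    region_label : canonical label of the region the points live in.
    region_area : area of that region in mm^2.
    """

    points: np.ndarray
    region_label: str = TUMOR
    region_area: float = float("nan")

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        self.points = pts

    @property
    def n_points(self) -> int:
        return int(len(self.points))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"x_mm": self.points[:, 0], "y_mm": self.points[:, 1]})


def _collect_polygons(geom) -> list[Polygon]:
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    raise GeometryError(f"expected (Multi)Polygon, got {geom.geom_type}")


def _segments_of(polygons: Sequence[Polygon]) -> np.ndarray:
    """All boundary segments (exterior and holes) as an (E, 2, 2) array."""
    segs = []
    for poly in polygons:
        rings = [poly.exterior, *poly.interiors]
        for ring in rings:
            coords = np.asarray(ring.coords, dtype=float)
            segs.append(np.stack([coords[:-1], coords[1:]], axis=1))
    return np.concatenate(segs, axis=0)


def _rect_bounds(polygons: Sequence[Polygon]) -> tuple | None:
    """Bounds if the geometry is a single hole-free axis-aligned rectangle."""
    if len(polygons) != 1 or polygons[0].interiors:
        return None
    poly = polygons[0]
    xmin, ymin, xmax, ymax = poly.bounds
    rect = Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])
    if math.isclose(poly.area, rect.area, rel_tol=1e-12) and rect.equals(poly):
        return (xmin, ymin, xmax, ymax)
    return None


def _min_segment_distance(xy: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment; O(N * E) but vectorized per edge."""
    x, y = xy[:, 0], xy[:, 1]
    d2 = np.full(len(xy), np.inf)
    for (ax, ay), (bx, by) in segments:
        abx, aby = bx - ax, by - ay
        denom = abx * abx + aby * aby
        if denom == 0.0:
            px, py = ax, ay
        else:
            t = np.clip(((x - ax) * abx + (y - ay) * aby) / denom, 0.0, 1.0)
            px, py = ax + t * abx, ay + t * aby
        np.minimum(d2, (x - px) ** 2 + (y - py) ** 2, out=d2)
    return np.sqrt(d2)


class _RegionIndex:
    """Per-label cache of geometry, segment array and rectangle fast path."""

    def __init__(self, polygons: Sequence[Polygon]):
        self.polygons = list(polygons)
        self.geometry = polygons[0] if len(polygons) == 1 else MultiPolygon(polygons)
        shapely.prepare(self.geometry)
        self.area = float(self.geometry.area)
        self.segments = _segments_of(polygons)
        self.rect = _rect_bounds(polygons)

    def distances(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        if self.rect is not None:
            xmin, ymin, xmax, ymax = self.rect
            dx = np.maximum(np.maximum(xmin - xy[:, 0], xy[:, 0] - xmax), 0.0)
            dy = np.maximum(np.maximum(ymin - xy[:, 1], xy[:, 1] - ymax), 0.0)
            return np.hypot(dx, dy)
        d = _min_segment_distance(xy, self.segments)
        inside = shapely.contains_xy(self.geometry, xy[:, 0], xy[:, 1])
        d[inside] = 0.0
        return d

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        # intersects_xy counts boundary points as inside, matching distance == 0
        return shapely.intersects_xy(self.geometry, xy[:, 0], xy[:, 1])


class RoiSet:
    """Labeled regions of interest of one slide, in mm.

    Parameters
    ----------
    regions : mapping of label -> Polygon | MultiPolygon | list of Polygons.
        Labels are canonicalized; the tumor region is mandatory downstream but
        not enforced at construction so partial sets can be inspected.
    """

    def __init__(self, regions: Mapping[str, object]):
        self._index: dict[str, _RegionIndex] = {}
        for label, geom in regions.items():
            key = canonical_label(label)
            if isinstance(geom, (list, tuple)):
                polys = []
                for g in geom:
                    polys.extend(_collect_polygons(g))
            else:
                polys = _collect_polygons(geom)
            for poly in polys:
                if not poly.is_valid:
                    raise GeometryError(f"invalid polygon under label {label!r}")
                if poly.area <= 0.0:
                    raise GeometryError(f"zero-area polygon under label {label!r}")
            if key in self._index:
                polys = self._index[key].polygons + polys
            self._index[key] = _RegionIndex(polys)

    # -- access ---------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return sorted(self._index)

    def __contains__(self, label: str) -> bool:
        try:
            return canonical_label(label) in self._index
        except LabelError:
            return False

    def geometry(self, label: str):
        return self._idx(label).geometry

    def polygons(self, label: str) -> list[Polygon]:
        return self._idx(label).polygons

    def area(self, label: str) -> float:
        return self._idx(label).area

    def _idx(self, label: str) -> _RegionIndex:
        key = canonical_label(label)
        if key not in self._index:
            raise LabelError(f"ROI label {key!r} not present; available: {self.labels}")
        return self._index[key]

    # -- queries --------------------------------------------------------
    def distances(self, xy: np.ndarray, label: str) -> np.ndarray:
        """Shortest distance (mm) from each point to the labeled region; 0 inside."""
        return self._idx(label).distances(xy)

    def contains(self, xy: np.ndarray, label: str) -> np.ndarray:
        return self._idx(label).contains(xy)

    def clip_pattern(self, pattern: PointPattern, label: str = TUMOR) -> PointPattern:
        """Restrict a pattern to the points inside the labeled region."""
        keep = self.contains(pattern.points, label)
        return PointPattern(pattern.points[keep], canonical_label(label), self.area(label))

    # -- I/O ------------------------------------------------------------
    @classmethod
    def from_geojson(cls, path, units: str = "mm", mpp: float | None = None) -> "RoiSet":
        """Load a FeatureCollection with a ``label`` property per feature.

        ``units='pixel'`` converts coordinates to mm via ``mpp`` (um/pixel),
        using the same 0-based top-left pixel origin as the segmentation.
        """
        with open(path) as fh:
            doc = json.load(fh)
        if units not in ("mm", "pixel"):
            raise ValueError("units must be 'mm' or 'pixel'")
        scale = 1.0
        if units == "pixel":
            if not mpp or mpp <= 0:
                raise ValueError("pixel units require a positive mpp")
            scale = mpp / 1000.0
        regions: dict[str, list[Polygon]] = {}
        for feat in doc.get("features", []):
            label = canonical_label(feat["properties"]["label"])
            geom = shapely_shape(feat["geometry"])
            for poly in _collect_polygons(geom):
                if scale != 1.0:
                    poly = shapely.transform(poly, lambda c: c * scale)
                regions.setdefault(label, []).append(poly)
        return cls(regions)

    def to_geojson(self, path) -> None:
        feats = []
        for label in self.labels:
            for poly in self.polygons(label):
                feats.append(
                    {
                        "type": "Feature",
                        "properties": {"label": label},
                        "geometry": shapely_mapping(poly),
                    }
                )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def distance_to_roi(point, roi: RoiSet, label: str) -> float:
    """Shortest distance (mm) from one point to a labeled region (0 inside)."""
    return float(roi.distances(np.asarray(point, dtype=float).reshape(1, 2), label)[0])


def distances_to_roi(points: np.ndarray, roi: RoiSet, label: str) -> np.ndarray:
    return roi.distances(points, label)


@dataclass
class DistanceDistribution:
    """Histogram of point-to-ROI distances on uniform bins starting at 0.

    ``counts`` are integers summing to ``n_points``; bins are half-open
    ``[lo, hi)`` with the final bin closed (numpy convention).
    """

    edges: np.ndarray
    counts: np.ndarray
    n_points: int = field(default=-1)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.n_points < 0:
            self.n_points = int(self.counts.sum())
        if self.edges[0] != 0.0:
            raise ValueError("first bin edge must be 0")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("counts/edges length mismatch")
        if int(self.counts.sum()) != self.n_points:
            raise ValueError("counts must sum to n_points")

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def extended_to(self, n_bins: int) -> "DistanceDistribution":
        """Same histogram padded with empty bins up to ``n_bins`` bins."""
        if n_bins < self.n_bins:
            raise ValueError("cannot shrink a histogram")
        if n_bins == self.n_bins:
            return self
        w = self.bin_width
        edges = np.arange(n_bins + 1, dtype=float) * w
        counts = np.zeros(n_bins, dtype=self.counts.dtype)
        counts[: self.n_bins] = self.counts
        return DistanceDistribution(edges, counts, self.n_points)


def _edges_for(max_distance: float, bin_width: float) -> np.ndarray:
    n_bins = max(1, int(math.ceil(max_distance / bin_width - 1e-12)))
    return np.arange(n_bins + 1, dtype=float) * bin_width


def histogram_distances(distances: np.ndarray, bin_width: float) -> DistanceDistribution:
    """Bin raw distances on [0, max rounded up to a bin edge]."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise DegenerateInputError("empty pattern: no distances to bin")
    edges = _edges_for(float(distances.max()), bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return DistanceDistribution(edges, counts, int(distances.size))


def distance_distribution(
    pattern: PointPattern, roi: RoiSet, label: str, bin_width: float = 0.1
) -> DistanceDistribution:
    """Binned distribution of shortest distances from a pattern to a labeled ROI."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if pattern.n_points == 0:
        raise DegenerateInputError("empty pattern is not evaluable")
    return histogram_distances(roi.distances(pattern.points, label), bin_width)
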