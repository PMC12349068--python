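"""Convex-peel summaries of persistence diagrams.

A persistence diagram is a planar point cloud (birth on x, death on y).  Its
100*alpha% convex peel is obtained by repeatedly stripping the vertices of
the current convex hull as long as at least a fraction alpha of the points
would remain; the peel polygon is the convex hull of the surviving points.
The peel's geometry — centroid, perimeter, area, and the filamentarity
shape index F = (P^2 - 4*pi*A) / (P^2 + 4*pi*A) — together with the point
count and mean lifetime of the full diagram give a 7-number summary per
diagram (14 per image across dims 0 and 1).

Filamentarity is 0 for a disk and approaches 1 for a line-like region, so
diagrams whose peel is long and thin (many short-lived features hugging the
diagonal) score high, while diagrams with long-lived features spread away
from the diagonal give rounder, larger peels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Polygon

from .persistence import PersistenceDiagram

__all__ = [
    "ConvexPeel",
    "TopoFeatureVector",
    "convex_peel",
    "peel_geometry",
    "diagram_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "npoints",
    "lifetime",
    "centroidx",
    "centroidy",
    "perimeter",
    "area",
    "filamentarity",
)


@dataclass(frozen=True)
class ConvexPeel:
    """Convex polygon retaining at least a fraction ``alpha`` of the points.

    ``polygon`` is the ordered (counter-clockwise) vertex list; degenerate
    clouds give a 2-vertex segment or a single point.
    """

    alpha: float
    polygon: np.ndarray  # (m, 2)
    retained_points: np.ndarray  # (k, 2)


@dataclass(frozen=True)
class TopoFeatureVector:
    """The seven diagram summaries.  Geometric entries are NaN for an empty
    diagram (missing-value propagation, not an error)."""

    npoints: int
    lifetime: float
    centroidx: float
    centroidy: float
    perimeter: float
    area: float
    filamentarity: float

    def to_dict(self, prefix: str = "") -> dict[str, float]:
        return {prefix + name: getattr(self, name) for name in FEATURE_NAMES}


def _extreme_locations(unique_pts: np.ndarray) -> np.ndarray:
    """Extreme points (hull vertices) of a deduplicated cloud.

    Collinear interior-of-edge points are *not* extreme; a collinear cloud
    has exactly its two endpoints extreme.
    """
    n = len(unique_pts)
    if n <= 2:
        return unique_pts
    try:
        hull = ConvexHull(unique_pts)
        return unique_pts[hull.vertices]
    except QhullError:
        # collinear: endpoints along the principal direction
        d = unique_pts - unique_pts.mean(axis=0)
        direction = d[np.argmax(np.einsum("ij,ij->i", d, d))]
        if not direction.any():
            return unique_pts[:1]
        proj = d @ direction
        return unique_pts[[np.argmin(proj), np.argmax(proj)]]


def convex_peel(points: np.ndarray, alpha: float = 0.95) -> ConvexPeel:
    """Strip whole convex-hull layers while >= ceil(alpha * n) points remain.

    A layer (the extreme points of the current cloud) is removed only if
    doing so leaves at least ``ceil(alpha * n)`` points, n being the original
    count.  Duplicated points at an extreme location are removed together.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    n = len(pts)
    target = math.ceil(alpha * n)

    current = pts
    while True:
        uniq = np.unique(current, axis=0)
        ext = _extreme_locations(uniq)
        if len(ext) >= len(uniq):
            break  # the whole cloud is its own hull layer
        on_layer = (current[:, None, :] == ext[None, :, :]).all(-1).any(-1)
        if len(current) - int(on_layer.sum()) < target:
            break
        current = current[~on_layer]

    uniq = np.unique(current, axis=0)
    if len(uniq) == 1:
        poly = uniq
    else:
        try:
            hull = ConvexHull(uniq)
            poly = uniq[hull.vertices]  # counter-clockwise
        except QhullError:
            poly = _extreme_locations(uniq)
    return ConvexPeel(alpha=alpha, polygon=poly, retained_points=current)


def peel_geometry(
    peel: ConvexPeel,
) -> tuple[float, float, float, float, float]:
    """(perimeter, area, centroidx, centroidy, filamentarity) of the peel.

    Degenerate segment: area 0, perimeter twice the length (the boundary
    traverses the segment both ways), filamentarity 1 (the line limit).
    Single point: all geometry 0, filamentarity defined as 0.
    """
    poly = np.asarray(peel.polygon, dtype=float)
    if len(poly) == 1:
        x, y = poly[0]
        return 0.0, 0.0, float(x), float(y), 0.0
    if len(poly) == 2:
        seg = LineString(poly)
        cx, cy = poly.mean(axis=0)
        return 2.0 * seg.length, 0.0, float(cx), float(cy), 1.0
    pg = Polygon(poly)
    p = pg.exterior.length
    a = pg.area
    c = pg.centroid
    fil = (p * p - 4 * math.pi * a) / (p * p + 4 * math.pi * a)
    return float(p), float(a), float(c.x), float(c.y), float(fil)


def diagram_features(
    diagram: PersistenceDiagram, alpha: float = 0.95
) -> TopoFeatureVector:
    """Summarize one diagram: npoints and mean lifetime over all finite
    points, plus the geometry of their 100*alpha% convex peel."""
    pts = diagram.points
    n = len(pts)
    if n == 0:
        return TopoFeatureVector(
            npoints=0, lifetime=0.0,
            centroidx=float("nan"), centroidy=float("nan"),
            perimeter=float("nan"), area=float("nan"),
            filamentarity=float("nan"),
        )
    lifetime = float(np.mean(pts[:, 1] - pts[:, 0]))
    peel = convex_peel(pts, alpha)
    p, a, cx, cy, fil = peel_geometry(peel)
    return TopoFeatureVector(
        npoints=n, lifetime=lifetime, centroidx=cx, centroidy=cy,
        perimeter=p, area=a, filamentarity=fil,
    )
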