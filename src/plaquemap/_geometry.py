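"""Internal planar-geometry helpers shared across modules.

All coordinates are millimetres.  Contours are open vertex lists of shape
``(n, 2)`` that are understood to be closed (last vertex connects back to
the first).
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import LinearRing, LineString, Point, Polygon

__all__ = [
    "as_points",
    "close_ring",
    "contour_polygon",
    "densify_contour",
    "ensure_ccw",
    "is_simple_contour",
    "polygon_area",
    "circle_points",
    "ellipse_points",
]


def as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    return pts


def close_ring(points: np.ndarray) -> np.ndarray:
    """Return the contour with the first vertex appended if not already closed."""
    pts = as_points(points)
    if np.allclose(pts[0], pts[-1]):
        return pts
    return np.vstack([pts, pts[:1]])


def dedup_closed(points: np.ndarray) -> np.ndarray:
    """Drop a duplicated closing vertex so the contour is stored open."""
    pts = as_points(points)
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def is_simple_contour(points) -> bool:
    pts = dedup_closed(as_points(points))
    if len(pts) < 3:
        return False
    ring = LinearRing(close_ring(pts))
    return ring.is_simple and ring.is_valid


def polygon_area(points) -> float:
    """Shoelace area of a closed contour, positive for either orientation."""
    pts = dedup_closed(as_points(points))
    if len(pts) < 3:
        raise ValueError("a contour needs at least 3 distinct vertices")
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed))


def signed_area(points) -> float:
    pts = dedup_closed(as_points(points))
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Reorient a contour counter-clockwise (viewed from +z) if needed."""
    pts = dedup_closed(as_points(points))
    if signed_area(pts) < 0:
        pts = pts[::-1].copy()
    return pts


def contour_polygon(points) -> Polygon:
    pts = dedup_closed(as_points(points))
    if len(pts) < 3:
        raise ValueError("a contour needs at least 3 distinct vertices")
    poly = Polygon(close_ring(pts))
    if not poly.is_valid:
        raise ValueError("contour is self-intersecting or degenerate")
    if poly.area <= 0:
        raise ValueError("contour has zero area")
    return poly


def densify_contour(points, max_spacing_mm: float) -> np.ndarray:
    """Resample a closed contour at arc spacing <= ``max_spacing_mm``.

    Returns an open vertex list; vertex count is chosen per edge so the
    original vertices are preserved.
    """
    pts = dedup_closed(as_points(points))
    out = []
    n = len(pts)
    for i in range(n):
        a = pts[i]
        b = pts[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / max_spacing_mm)))
        t = np.arange(k) / k
        out.append(a[None, :] * (1 - t[:, None]) + b[None, :] * t[:, None])
    return np.vstack(out)


def contour_linestring(points) -> LineString:
    return LineString(close_ring(as_points(points)))


def points_in_polygon(xy: np.ndarray, contour_points) -> np.ndarray:
    """Vectorised point-in-polygon test (boundary counts as inside)."""
    poly = contour_polygon(contour_points)
    prepared = shapely.prepared.prep(poly)
    return np.array([prepared.intersects(Point(p)) for p in xy], dtype=bool)


def contains_xy(contour_points, x, y) -> np.ndarray:
    poly = contour_polygon(contour_points)
    return shapely.contains_xy(poly, x, y)


def circle_points(radius: float, center=(0.0, 0.0), n: int = 360) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def ellipse_points(a: float, b: float, center=(0.0, 0.0), n: int = 360) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(th), center[1] + b * np.sin(th)])
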