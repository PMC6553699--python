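"""Per-slice lumen centerpoints via maximal inscribed circles.

The per-section centerpoint is the interior point maximising distance to
the lumen contour — the 2D maximal inscribed circle, located through the
Voronoi diagram of the (densified) contour vertices and polished by a
local optimisation.  The per-section centers are then moving-average
smoothed along z to form the centerline used as origin for radial
binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import Voronoi
from shapely.geometry import Point

from . import _geometry as geom
from .imaging_io import ContourStack

__all__ = ["Centerline", "max_inscribed_circle_center", "compute_centerline"]


@dataclass
class Centerline:
    """Ordered per-section centerpoints with inscribed radii."""

    slice_indices: np.ndarray
    points: np.ndarray  # (n, 3) x, y, z in mm
    inscribed_radius_mm: np.ndarray

    def __post_init__(self) -> None:
        self.slice_indices = np.asarray(self.slice_indices, dtype=int)
        self.points = np.asarray(self.points, dtype=float)
        self.inscribed_radius_mm = np.asarray(self.inscribed_radius_mm, dtype=float)
        if np.any(np.diff(self.points[:, 2]) <= 0):
            raise ValueError("centerline z must be strictly increasing")

    def centerpoint(self, slice_index: int) -> np.ndarray:
        pos = np.nonzero(self.slice_indices == slice_index)[0]
        if len(pos) != 1:
            raise KeyError(f"no centerline point for slice {slice_index}")
        return self.points[pos[0], :2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_index": self.slice_indices,
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "radius_mm": self.inscribed_radius_mm,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def max_inscribed_circle_center(
    contour_points, *, densify_mm: float = 0.05
) -> tuple[np.ndarray, float]:
    """Center and radius of the maximal circle inscribed in a closed contour.

    Candidate centers are the interior Voronoi vertices of the densified
    boundary (the discrete medial axis); the best candidate is refined by
    Nelder-Mead on the distance-to-boundary function.

    Raises
    ------
    ValueError
        For degenerate (zero-area or non-simple) contours.
    """
    pts = geom.dedup_closed(geom.as_points(contour_points))
    poly = geom.contour_polygon(pts)  # validates simplicity / area
    boundary = poly.exterior

    dense = geom.densify_contour(pts, densify_mm)
    # subsample if extremely dense: Voronoi cost grows, accuracy does not
    if len(dense) > 4000:
        dense = dense[:: len(dense) // 4000 + 1]
    vor = Voronoi(dense)
    candidates = vor.vertices
    keep = geom.contains_xy(pts, candidates[:, 0], candidates[:, 1])
    candidates = candidates[keep]
    if len(candidates) == 0:
        candidates = np.asarray(poly.representative_point().coords)

    dists = np.array([boundary.distance(Point(c)) for c in candidates])
    best = candidates[int(np.argmax(dists))]

    def neg_dist(p):
        pt = Point(p)
        if not poly.contains(pt):
            return pt.distance(boundary)  # positive: outside is penalised
        return -boundary.distance(pt)

    res = minimize(neg_dist, best, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-9})
    center = res.x if -res.fun >= dists.max() else best
    radius = float(boundary.distance(Point(center)))
    return np.asarray(center, dtype=float), radius


def compute_centerline(
    lumen_contours: ContourStack, smoothing_window: int = 3
) -> Centerline:
    """Centerline from per-slice maximal-inscribed-circle centers.

    Centers are moving-average smoothed along z with the given window
    (window 1 disables smoothing).  If smoothing pushes a centerpoint
    outside its lumen contour, the unsmoothed center is kept for that
    slice.

    Raises
    ------
    ValueError
        If fewer than 2 sections are present or a section lacks a lumen
        contour.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    lumen = [c for c in lumen_contours if c.structure == "lumen"]
    if len(lumen) < 2:
        raise ValueError("centerline needs at least 2 sections with lumen contours")
    lumen.sort(key=lambda c: c.slice_index)
    expected = range(lumen[0].slice_index, lumen[-1].slice_index + 1)
    present = {c.slice_index for c in lumen}
    missing = sorted(set(expected) - present)
    if missing:
        raise ValueError(f"missing lumen contour for slice(s) {missing}")

    centers = []
    radii = []
    for c in lumen:
        ctr, r = max_inscribed_circle_center(c.points)
        centers.append(ctr)
        radii.append(r)
    centers = np.asarray(centers)

    smoothed = centers.copy()
    half = smoothing_window // 2
    if half:
        for i in range(len(centers)):
            # shrink the window symmetrically at the ends so linear trends
            # pass through unbiased
            h = min(half, i, len(centers) - 1 - i)
            smoothed[i] = centers[i - h : i + h + 1].mean(axis=0)
        for i, c in enumerate(lumen):  # smoothing must not exit the lumen
            if not bool(geom.contains_xy(c.points, smoothed[i, 0], smoothed[i, 1])):
                smoothed[i] = centers[i]

    points = np.column_stack([smoothed, [c.z_mm for c in lumen]])
    return Centerline(
        np.array([c.slice_index for c in lumen]), points, np.asarray(radii)
    )
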