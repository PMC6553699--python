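"""Radial binning of sections and per-bin WSS / plaque-thickness statistics.

Each histology section is subdivided into ``n_bins`` (default 8) angular
wedges about its centerline point.  The wedge convention: angles are
measured counter-clockwise from the +x axis of the en-face frame,
normalised to [0, 2pi); wedges are half-open, a boundary angle belongs
to the higher-index wedge.  The surface WSS scalar is projected onto a
section by pooling all mesh vertices within the +-0.3 mm axial window
(nearest-neighbour in the sense of vertex values, no interpolation) and
taking per-wedge mean/min/max.  Bins containing no vertex are marked
empty, never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from . import _geometry as geom
from .imaging_io import BIN_TABLE_COLUMNS, SurfaceScalarField

__all__ = [
    "ProjectionParams",
    "assign_radial_bin",
    "assign_radial_bins",
    "project_wss_to_section",
    "plaque_thickness_per_bin",
    "component_area",
    "build_bin_table",
]


@dataclass
class ProjectionParams:
    """Axial window and angular-wedge configuration."""

    axial_halfwidth_mm: float = 0.3
    n_bins: int = 8
    bin_zero_direction_deg: float = 0.0  # wedge-0 lower edge, CCW from +x

    def __post_init__(self) -> None:
        if self.axial_halfwidth_mm <= 0:
            raise ValueError("axial_halfwidth_mm must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def assign_radial_bins(
    points, centerpoint, params: ProjectionParams | None = None
) -> np.ndarray:
    """Vectorised wedge assignment for an (n, 2) point array."""
    params = params or ProjectionParams()
    pts = geom.as_points(points)
    d = pts - np.asarray(centerpoint, dtype=float)
    if np.any(np.all(d == 0, axis=1)):
        raise ValueError("point coincides with the centerpoint; angle undefined")
    theta = np.arctan2(d[:, 1], d[:, 0]) - np.deg2rad(params.bin_zero_direction_deg)
    theta = np.mod(theta, 2 * np.pi)
    bins = np.floor(params.n_bins * theta / (2 * np.pi)).astype(int)
    return np.minimum(bins, params.n_bins - 1)  # guard the theta == 2*pi rounding edge


def assign_radial_bin(point, centerpoint, params: ProjectionParams | None = None) -> int:
    """Wedge index of a single point; see module docstring for the convention."""
    return int(assign_radial_bins(np.asarray(point, dtype=float)[None, :], centerpoint, params)[0])


def project_wss_to_section(
    field: SurfaceScalarField,
    z_mm: float,
    centerpoint,
    params: ProjectionParams | None = None,
) -> pd.DataFrame:
    """Per-bin (mean, min, max) WSS for one section.

    Pools every mesh vertex with ``|vertex_z - z_mm| <= axial_halfwidth``
    and groups by radial wedge.  Returns a frame indexed by ``bin_index``
    with columns ``mean_wss_pa``, ``min_wss_pa``, ``max_wss_pa``,
    ``n_vertices`` and ``empty``; empty bins carry NaN statistics.

    Raises
    ------
    ValueError
        If no vertex falls inside the axial window.
    """
    params = params or ProjectionParams()
    dz = np.abs(field.vertices[:, 2] - float(z_mm))
    # relative epsilon so lattice vertices exactly at the window edge are
    # kept symmetrically despite float rounding
    in_window = dz <= params.axial_halfwidth_mm * (1 + 1e-9)
    if not in_window.any():
        raise ValueError(
            f"no mesh vertices within +-{params.axial_halfwidth_mm} mm of z={z_mm} mm"
        )
    xy = field.vertices[in_window, :2]
    values = field.scalar[in_window]
    bins = assign_radial_bins(xy, centerpoint, params)

    rows = []
    for b in range(params.n_bins):
        sel = bins == b
        n = int(sel.sum())
        if n == 0:
            rows.append((b, np.nan, np.nan, np.nan, 0, True))
        else:
            v = values[sel]
            rows.append((b, float(v.mean()), float(v.min()), float(v.max()), n, False))
    return pd.DataFrame(
        rows,
        columns=["bin_index", "mean_wss_pa", "min_wss_pa", "max_wss_pa", "n_vertices", "empty"],
    ).set_index("bin_index")


def plaque_thickness_per_bin(
    lumen_points,
    media_points,
    centerpoint,
    params: ProjectionParams | None = None,
    *,
    sample_spacing_mm: float = 0.05,
) -> np.ndarray:
    """Per-bin mean shortest lumen-to-media distance (mm).

    The lumen contour is densely resampled (arc spacing <=
    ``sample_spacing_mm``); each sample's shortest Euclidean distance to
    the media polyline is computed, samples are grouped into radial
    wedges and averaged per wedge.  Bins receiving no lumen sample are
    NaN.

    Raises
    ------
    ValueError
        If the contours intersect or the media does not enclose the lumen.
    """
    params = params or ProjectionParams()
    lumen_poly = geom.contour_polygon(lumen_points)
    media_poly = geom.contour_polygon(media_points)
    media_ring = geom.contour_linestring(media_points)
    if lumen_poly.exterior.crosses(media_ring):
        raise ValueError("lumen and media contours intersect")
    if not media_poly.covers(lumen_poly):
        raise ValueError("media contour must enclose the lumen contour")

    samples = geom.densify_contour(lumen_points, sample_spacing_mm)
    dists = np.array([media_ring.distance(Point(p)) for p in samples])
    bins = assign_radial_bins(samples, centerpoint, params)
    out = np.full(params.n_bins, np.nan)
    for b in range(params.n_bins):
        sel = bins == b
        if sel.any():
            out[b] = float(dists[sel].mean())
    return out


def component_area(contour_points) -> float:
    """Shoelace area (mm^2) of a plaque-component contour, orientation-free.

    Raises
    ------
    ValueError
        For self-intersecting contours.
    """
    if not geom.is_simple_contour(contour_points):
        raise ValueError("contour is self-intersecting or degenerate")
    return geom.polygon_area(contour_points)


def section_overlay(
    field: SurfaceScalarField,
    lumen_points,
    z_mm: float,
    centerpoint,
    path,
    params: ProjectionParams | None = None,
) -> None:
    """Visual QC figure for one section: in-window WSS vertices colour-mapped
    on the lumen, with the radial-bin spokes and the lumen outline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = params or ProjectionParams()
    dz = np.abs(field.vertices[:, 2] - float(z_mm))
    sel = dz <= params.axial_halfwidth_mm * (1 + 1e-9)
    xy = field.vertices[sel, :2]
    values = field.scalar[sel]
    cx, cy = centerpoint
    lumen = geom.close_ring(geom.as_points(lumen_points))

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, s=6, cmap="viridis")
    ax.plot(lumen[:, 0], lumen[:, 1], "k-", lw=0.8)
    r_spoke = 1.15 * np.max(np.linalg.norm(lumen - [cx, cy], axis=1))
    for b in range(params.n_bins):
        ang = np.deg2rad(params.bin_zero_direction_deg) + 2 * np.pi * b / params.n_bins
        ax.plot([cx, cx + r_spoke * np.cos(ang)], [cy, cy + r_spoke * np.sin(ang)],
                color="0.6", lw=0.6)
    ax.plot([cx], [cy], "r+")
    ax.set_aspect("equal")
    ax.set_title(f"z = {z_mm:g} mm")
    fig.colorbar(sc, ax=ax, label="WSS (Pa)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def build_bin_table(section_records: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble one row per (specimen, section, bin) into the bin table.

    Each record must provide ``specimen_id``, ``slice_index``, ``z_mm``,
    ``bin_index``, ``mean_wss_pa``, ``min_wss_pa``, ``max_wss_pa`` and
    ``plaque_thickness_mm``; ``error_flags`` (string such as
    ``"type1+type2"``) and ``included`` default to no flags / included.

    Raises
    ------
    ValueError
        On duplicate (specimen, slice, bin) keys.
    """
    rows = []
    for rec in section_records:
        row = dict(rec)
        row.setdefault("error_flags", "")
        row.setdefault("included", row["error_flags"] == "")
        rows.append(row)
    table = pd.DataFrame(rows, columns=BIN_TABLE_COLUMNS)
    if len(table) == 0:
        return pd.DataFrame(columns=BIN_TABLE_COLUMNS)
    if table.duplicated(subset=["specimen_id", "slice_index", "bin_index"]).any():
        dup = table[table.duplicated(subset=["specimen_id", "slice_index", "bin_index"])]
        key = dup.iloc[0]
        raise ValueError(
            "duplicate bin key "
            f"({key['specimen_id']}, {key['slice_index']}, {key['bin_index']})"
        )
    table["slice_index"] = table["slice_index"].astype(int)
    table["bin_index"] = table["bin_index"].astype(int)
    table["included"] = table["included"].astype(bool)
    return table.reset_index(drop=True)
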