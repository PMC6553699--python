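"""In-plane transforms and their composition into a shared image domain.

All transforms act on 2D points in mm.  Sections are registered within
matched slices (rigid z-anchoring by slice index), so z passes through
unchanged when a transform is applied to contour stacks or surface
vertices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .. import _geometry as geom
from ..imaging_io import ContourStack, SurfaceScalarField

__all__ = [
    "SimilarityTransform2D",
    "BSplineTransform2D",
    "TransformChain",
    "compose_similarity",
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
]


@dataclass
class SimilarityTransform2D:
    """Rotation + isotropic scale + translation: ``T(x) = s R x + t``."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.rotation_deg = float(self.rotation_deg)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        self.translation_mm = (
            float(self.translation_mm[0]),
            float(self.translation_mm[1]),
        )

    @property
    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        pts = geom.as_points(points)
        return pts @ self.matrix.T + np.asarray(self.translation_mm)

    __call__ = apply

    def inverse(self) -> "SimilarityTransform2D":
        inv_mat = np.linalg.inv(self.matrix)
        t = -inv_mat @ np.asarray(self.translation_mm)
        return SimilarityTransform2D(
            rotation_deg=-self.rotation_deg,
            scale=1.0 / self.scale,
            translation_mm=(t[0], t[1]),
        )

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.rotation_deg) <= tol
            and abs(self.scale - 1) <= tol
            and np.allclose(self.translation_mm, 0, atol=tol)
        )


def compose_similarity(
    outer: SimilarityTransform2D, inner: SimilarityTransform2D
) -> SimilarityTransform2D:
    """Similarity equal to ``outer(inner(x))``."""
    t = outer.apply(np.asarray(inner.translation_mm)[None, :])[0]
    return SimilarityTransform2D(
        rotation_deg=outer.rotation_deg + inner.rotation_deg,
        scale=outer.scale * inner.scale,
        translation_mm=(t[0], t[1]),
    )


def _cubic_bspline_weights(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at fractional offset t in [0,1).

    Returns an array of shape (4, len(t)).
    """
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ]
    )


@dataclass
class BSplineTransform2D:
    """Free-form deformation on a uniform cubic B-spline control grid.

    ``coefficients[iy, ix]`` is the (dx, dy) displacement (mm) of the
    control point at ``grid_origin + (ix * hx, iy * hy)``.  The warp is
    ``T(x) = x + disp(x)`` with C2-smooth ``disp`` by construction;
    points outside the grid's full-support region get zero displacement.
    """

    grid_origin_mm: tuple[float, float]
    grid_spacing_mm: tuple[float, float]
    coefficients: np.ndarray  # (ny, nx, 2)

    def __post_init__(self) -> None:
        self.grid_origin_mm = tuple(float(v) for v in self.grid_origin_mm)
        self.grid_spacing_mm = tuple(float(v) for v in self.grid_spacing_mm)
        if any(h <= 0 for h in self.grid_spacing_mm):
            raise ValueError("grid spacing must be > 0")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 3 or self.coefficients.shape[2] != 2:
            raise ValueError("coefficients must have shape (ny, nx, 2)")

    @property
    def control_grid_shape(self) -> tuple[int, int]:
        return self.coefficients.shape[:2]

    @classmethod
    def for_domain(
        cls,
        xmin: float,
        xmax: float,
        ymin: float,
        ymax: float,
        grid_spacing_mm: float,
    ) -> "BSplineTransform2D":
        """Zero transform whose grid fully supports ``[xmin,xmax]×[ymin,ymax]``."""
        hx = hy = float(grid_spacing_mm)
        ox, oy = xmin - hx, ymin - hy
        nx = int(np.ceil((xmax - ox) / hx)) + 3
        ny = int(np.ceil((ymax - oy) / hy)) + 3
        return cls((ox, oy), (hx, hy), np.zeros((ny, nx, 2)))

    def _support(self, points: np.ndarray):
        pts = geom.as_points(points)
        u = (pts[:, 0] - self.grid_origin_mm[0]) / self.grid_spacing_mm[0]
        v = (pts[:, 1] - self.grid_origin_mm[1]) / self.grid_spacing_mm[1]
        ix0 = np.floor(u).astype(int) - 1
        iy0 = np.floor(v).astype(int) - 1
        ny, nx = self.control_grid_shape
        inside = (ix0 >= 0) & (ix0 + 3 < nx) & (iy0 >= 0) & (iy0 + 3 < ny)
        tx = u - np.floor(u)
        ty = v - np.floor(v)
        return ix0, iy0, tx, ty, inside

    def displacement(self, points) -> np.ndarray:
        pts = geom.as_points(points)
        ix0, iy0, tx, ty, inside = self._support(pts)
        disp = np.zeros_like(pts)
        if not inside.any():
            return disp
        ix0, iy0 = ix0[inside], iy0[inside]
        wx = _cubic_bspline_weights(tx[inside])  # (4, m)
        wy = _cubic_bspline_weights(ty[inside])
        acc = np.zeros((inside.sum(), 2))
        for a in range(4):
            for b in range(4):
                w = (wy[a] * wx[b])[:, None]
                acc += w * self.coefficients[iy0 + a, ix0 + b]
        disp[inside] = acc
        return disp

    def basis_weights(self, points):
        """Per-point 16 control indices and weights (for gradient scatter)."""
        pts = geom.as_points(points)
        ix0, iy0, tx, ty, inside = self._support(pts)
        wx = _cubic_bspline_weights(tx)
        wy = _cubic_bspline_weights(ty)
        ny, nx = self.control_grid_shape
        idx = np.zeros((len(pts), 16), dtype=int)
        wgt = np.zeros((len(pts), 16))
        k = 0
        for a in range(4):
            for b in range(4):
                idx[:, k] = np.clip(iy0 + a, 0, ny - 1) * nx + np.clip(ix0 + b, 0, nx - 1)
                wgt[:, k] = wy[a] * wx[b]
                k += 1
        wgt[~inside] = 0.0
        return idx, wgt

    def apply(self, points) -> np.ndarray:
        pts = geom.as_points(points)
        return pts + self.displacement(pts)

    __call__ = apply

    def invert_points(self, points, tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
        """Numerically invert the warp at the given points (Picard iteration).

        Converges for the coarse, small-magnitude deformations used here
        (displacement Lipschitz constant < 1).
        """
        pts = geom.as_points(points)
        x = pts.copy()
        for _ in range(max_iter):
            x_new = pts - self.displacement(x)
            if np.max(np.abs(x_new - x)) < tol:
                return x_new
            x = x_new
        return x

    def max_abs_coefficient(self) -> float:
        return float(np.max(np.abs(self.coefficients))) if self.coefficients.size else 0.0


@dataclass
class TransformChain:
    """Ordered transform composition with domain-label bookkeeping.

    Each step is ``(transform, source_domain, target_domain)``; adjacent
    steps must chain (target of step i equals source of step i+1).  The
    composed mapping applies steps in order and acts on points, contour
    stacks and surface meshes (in-plane; z is preserved).
    """

    steps: list[tuple[object, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for (_, _, tgt), (_, src, _) in zip(self.steps, self.steps[1:]):
            if tgt != src:
                raise ValueError(
                    f"transform chain broken: step target {tgt!r} != next source {src!r}"
                )

    @property
    def source(self) -> str | None:
        return self.steps[0][1] if self.steps else None

    @property
    def target(self) -> str | None:
        return self.steps[-1][2] if self.steps else None

    def append(self, transform, source: str, target: str) -> None:
        self.steps.append((transform, source, target))
        self.validate()

    def apply(self, points) -> np.ndarray:
        pts = geom.as_points(points)
        for transform, _, _ in self.steps:
            pts = transform.apply(pts)
        return pts

    __call__ = apply

    def apply_to_contours(self, stack: ContourStack) -> ContourStack:
        return stack.map_points(self.apply)

    def apply_to_surface(self, fieldobj: SurfaceScalarField) -> SurfaceScalarField:
        xy = self.apply(fieldobj.vertices[:, :2])
        vertices = np.column_stack([xy, fieldobj.vertices[:, 2]])
        return SurfaceScalarField(vertices, fieldobj.faces.copy(), fieldobj.scalar.copy())


def compose(chain: TransformChain) -> TransformChain:
    """Validate and return the chain as a callable point mapping."""
    chain.validate()
    return chain


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def transform_to_dict(t) -> dict:
    if isinstance(t, SimilarityTransform2D):
        return {
            "type": "similarity2d",
            "rotation_deg": t.rotation_deg,
            "scale": t.scale,
            "translation_mm": list(t.translation_mm),
        }
    if isinstance(t, BSplineTransform2D):
        return {
            "type": "bspline2d",
            "grid_origin_mm": list(t.grid_origin_mm),
            "grid_spacing_mm": list(t.grid_spacing_mm),
            "coefficients": t.coefficients.tolist(),
        }
    if isinstance(t, TransformChain):
        return {
            "type": "chain",
            "steps": [
                {"source": src, "target": tgt, "transform": transform_to_dict(tr)}
                for tr, src, tgt in t.steps
            ],
        }
    raise TypeError(f"cannot serialize transform of type {type(t).__name__}")


def transform_from_dict(d: dict):
    kind = d.get("type")
    if kind == "similarity2d":
        return SimilarityTransform2D(
            d["rotation_deg"], d["scale"], tuple(d["translation_mm"])
        )
    if kind == "bspline2d":
        return BSplineTransform2D(
            tuple(d["grid_origin_mm"]),
            tuple(d["grid_spacing_mm"]),
            np.asarray(d["coefficients"]),
        )
    if kind == "chain":
        return TransformChain(
            [
                (transform_from_dict(s["transform"]), s["source"], s["target"])
                for s in d["steps"]
            ]
        )
    raise ValueError(f"unknown transform type tag: {kind!r}")


def save_transform(t, path) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(t), indent=1))


def load_transform(path):
    return transform_from_dict(json.loads(Path(path).read_text()))
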