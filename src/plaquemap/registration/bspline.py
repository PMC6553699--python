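"""Contour-driven non-rigid B-spline registration.

The moving contours must already be rigidly pre-registered to the fixed
contours.  Fixed contours are rasterized to signed distance maps (0.1
mm/pixel by default); the mean-squares metric is the mean squared signed
distance of the warped moving contour samples, which is zero exactly
when the warped moving contours lie on the fixed ones.  The metric is
minimised over the B-spline control-point displacements by an
adaptive-step stochastic gradient descent with a fixed sampling seed:
candidate steps are only *accepted* when the full-sample metric
decreases, so the accepted-iteration metric trace is monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from .. import _geometry as geom
from ..imaging_io import ContourStack
from .transforms import BSplineTransform2D

__all__ = ["BSplineRegistrationParams", "register_contours_bspline"]


@dataclass
class BSplineRegistrationParams:
    """Knobs for :func:`register_contours_bspline`.

    Defaults: 5 mm control-grid spacing, 500 iterations, signed distance
    maps at 0.1 mm/pixel, seeded subsampling of the contour points.
    """

    grid_spacing_mm: float = 5.0
    iterations: int = 500
    raster_pixel_mm: float = 0.1
    margin_mm: float = 4.0
    sample_spacing_mm: float = 0.1
    n_samples_per_iteration: int = 2000
    initial_step_mm: float = 0.3
    min_step_mm: float = 1e-5
    seed: int = 0


def _matched_pairs(fixed: ContourStack, moving: ContourStack):
    pairs = []
    for c in moving:
        if fixed.has(c.slice_index, c.structure):
            pairs.append((fixed.get(c.slice_index, c.structure), c))
    if not pairs:
        raise ValueError("no matching (slice, structure) contours between stacks")
    return pairs


def _signed_distance_map(contour_points, xs, ys, pixel_mm):
    inside = geom.contains_xy(
        contour_points,
        np.repeat(xs[None, :], len(ys), axis=0).ravel(),
        np.repeat(ys[:, None], len(xs), axis=1).ravel(),
    ).reshape(len(ys), len(xs))
    # positive outside, negative inside; edt measures to the nearest
    # differently-labelled pixel, offset half a pixel to centre the zero set
    d_out = distance_transform_edt(~inside) * pixel_mm
    d_in = distance_transform_edt(inside) * pixel_mm
    return np.where(inside, -(d_in - 0.5 * pixel_mm), d_out - 0.5 * pixel_mm)


def register_contours_bspline(
    fixed: ContourStack,
    moving: ContourStack,
    params: BSplineRegistrationParams | None = None,
) -> BSplineTransform2D:
    """Fit one in-plane B-spline warp driving moving contours onto fixed ones.

    All matched (slice, structure) pairs contribute jointly to a single
    2D transform (sections share the in-plane deformation; z is anchored
    by slice index).  Returns the fitted :class:`BSplineTransform2D`
    with diagnostics attached: ``metric_trace_`` (accepted iterations),
    ``initial_metric_``, ``final_metric_`` and ``converged_``.

    Raises
    ------
    ValueError
        If any matched pair's bounding boxes do not overlap (rigid
        pre-registration missing) or no structures match.
    """
    params = params or BSplineRegistrationParams()
    pairs = _matched_pairs(fixed, moving)

    all_pts = []
    for f, m in pairs:
        fmin, fmax = f.points.min(axis=0), f.points.max(axis=0)
        mmin, mmax = m.points.min(axis=0), m.points.max(axis=0)
        if np.any(fmax < mmin) or np.any(mmax < fmin):
            raise ValueError(
                f"contour bounding boxes do not overlap for slice "
                f"{f.slice_index}/{f.structure}; run rigid pre-registration first"
            )
        all_pts.append(f.points)
        all_pts.append(m.points)
    all_pts = np.vstack(all_pts)
    lo = all_pts.min(axis=0) - params.margin_mm
    hi = all_pts.max(axis=0) + params.margin_mm

    px = params.raster_pixel_mm
    xs = np.arange(lo[0], hi[0] + px, px)
    ys = np.arange(lo[1], hi[1] + px, px)

    # one SDM (plus gradient) per matched pair, on a shared grid
    sdms = np.empty((len(pairs), len(ys), len(xs)))
    for g, (f, _) in enumerate(pairs):
        sdms[g] = _signed_distance_map(f.points, xs, ys, px)
    gy, gx = np.gradient(sdms, px, axis=(1, 2))

    samples = []
    groups = []
    for g, (_, m) in enumerate(pairs):
        pts = geom.densify_contour(m.points, params.sample_spacing_mm)
        samples.append(pts)
        groups.append(np.full(len(pts), g))
    samples = np.vstack(samples)
    groups = np.concatenate(groups)
    n_total = len(samples)

    def interp(arr, pts, gid):
        rows = (pts[:, 1] - lo[1]) / px
        cols = (pts[:, 0] - lo[0]) / px
        return map_coordinates(
            arr, np.vstack([gid.astype(float), rows, cols]), order=1, mode="nearest"
        )

    transform = BSplineTransform2D.for_domain(
        lo[0], hi[0], lo[1], hi[1], params.grid_spacing_mm
    )
    ny, nx = transform.control_grid_shape
    coeff = transform.coefficients

    def full_metric(c):
        transform.coefficients = c
        warped = transform.apply(samples)
        v = interp(sdms, warped, groups)
        return float(np.mean(v**2))

    rng = np.random.default_rng(params.seed)
    metric = full_metric(coeff)
    initial_metric = metric
    trace = [(0, metric)]
    step = params.initial_step_mm

    for it in range(1, params.iterations + 1):
        if step < params.min_step_mm:
            break
        if n_total > params.n_samples_per_iteration:
            sel = rng.choice(n_total, params.n_samples_per_iteration, replace=False)
        else:
            sel = slice(None)
        pts = samples[sel]
        gid = groups[sel]
        transform.coefficients = coeff
        warped = transform.apply(pts)
        v = interp(sdms, warped, gid)
        dx = interp(gx, warped, gid)
        dy = interp(gy, warped, gid)
        idx, wgt = transform.basis_weights(pts)

        grad = np.zeros((ny * nx, 2))
        np.add.at(grad[:, 0], idx.ravel(), (2.0 * v * dx)[:, None].repeat(16, 1).ravel() * wgt.ravel())
        np.add.at(grad[:, 1], idx.ravel(), (2.0 * v * dy)[:, None].repeat(16, 1).ravel() * wgt.ravel())
        grad /= len(pts)
        gmax = np.max(np.abs(grad))
        if gmax == 0:
            break
        candidate = coeff - (step / gmax) * grad.reshape(ny, nx, 2)
        cand_metric = full_metric(candidate)
        if cand_metric < metric:
            coeff = candidate
            metric = cand_metric
            trace.append((it, metric))
            step *= 1.2
        else:
            step *= 0.5

    transform.coefficients = coeff
    transform.metric_trace_ = trace
    transform.initial_metric_ = initial_metric
    transform.final_metric_ = metric
    transform.converged_ = metric <= initial_metric
    if metric > initial_metric:
        warnings.warn(
            f"B-spline registration did not converge (final metric {metric:.4g} "
            f"> initial {initial_metric:.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return transform
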