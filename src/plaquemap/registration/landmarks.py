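"""Point-based similarity fitting and en-face photo stack assembly."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .. import _geometry as geom
from ..imaging_io import PlanarImage, VolumeImage
from .transforms import SimilarityTransform2D, compose_similarity

__all__ = ["fit_similarity_from_landmarks", "stack_enface_photos"]


def fit_similarity_from_landmarks(
    fixed_points,
    moving_points,
    *,
    allow_scale: bool = True,
) -> SimilarityTransform2D:
    """Least-squares similarity ``T`` minimising ``sum ||T(moving_i) - fixed_i||^2``.

    Closed-form solution via the SVD of the cross-covariance of the
    centred point sets (Umeyama/Procrustes).  With ``allow_scale=False``
    the fit is rigid (rotation + translation only), as used for en-face
    photo stacking where all photos share one calibrated pixel size.

    The fitted transform carries the RMS residual as ``rms_residual_mm_``.

    Raises
    ------
    ValueError
        On index-mismatched lists, fewer than two pairs, or a degenerate
        (all-coincident) point configuration.
    """
    fixed = geom.as_points(fixed_points)
    moving = geom.as_points(moving_points)
    if len(fixed) != len(moving):
        raise ValueError(
            f"point lists must be index-matched: {len(fixed)} fixed vs "
            f"{len(moving)} moving"
        )
    if len(fixed) < 2:
        raise ValueError("at least 2 point pairs are required in 2D")

    mu_f = fixed.mean(axis=0)
    mu_m = moving.mean(axis=0)
    fc = fixed - mu_f
    mc = moving - mu_m
    var_m = float(np.sum(mc**2)) / len(moving)
    if var_m <= 1e-24:
        raise ValueError("degenerate configuration: moving points are coincident")
    if float(np.sum(fc**2)) <= 1e-24:
        raise ValueError("degenerate configuration: fixed points are coincident")

    cov = fc.T @ mc / len(moving)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    scale = float(np.trace(np.diag(S) @ D) / var_m) if allow_scale else 1.0
    if scale <= 0:
        raise ValueError("degenerate configuration: non-positive fitted scale")
    rotation_deg = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
    t = mu_f - scale * (R @ mu_m)
    fit = SimilarityTransform2D(rotation_deg, scale, (t[0], t[1]))
    resid = fit.apply(moving) - fixed
    fit.rms_residual_mm_ = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return fit


def stack_enface_photos(
    photos: Sequence[PlanarImage],
    *,
    output_pixel_size_mm: float | None = None,
) -> tuple[VolumeImage, list[SimilarityTransform2D]]:
    """Assemble serial en-face photos into a 3D stack in photo 0's frame.

    Photo ``k`` is registered to photo ``k-1`` by a rigid (rotation +
    translation, scale fixed at 1) landmark fit on their shared labels;
    transforms are accumulated so every photo lives in photo 0's frame.
    The output volume samples all photos on photo 0's grid (or a stated
    common pixel size) with section z locations preserved.

    Returns the stacked volume and, per photo, the accumulated transform
    mapping that photo's coordinates into photo 0's frame.
    """
    from scipy.ndimage import map_coordinates

    if len(photos) == 0:
        raise ValueError("no photos to stack")
    accumulated = [SimilarityTransform2D()]
    for k in range(1, len(photos)):
        prev, cur = photos[k - 1], photos[k]
        shared = sorted(set(prev.landmarks) & set(cur.landmarks))
        if len(shared) < 2:
            raise ValueError(
                f"photos {k - 1} and {k} share {len(shared)} landmark label(s); "
                "at least 2 are required"
            )
        step = fit_similarity_from_landmarks(
            prev.landmark_array(shared), cur.landmark_array(shared), allow_scale=False
        )
        accumulated.append(compose_similarity(accumulated[-1], step))

    pixel = float(output_pixel_size_mm or photos[0].pixel_size_mm)
    ref = photos[0]
    nrow, ncol = ref.pixels.shape[:2]
    out_ncol = int(np.ceil(ncol * ref.pixel_size_mm / pixel))
    out_nrow = int(np.ceil(nrow * ref.pixel_size_mm / pixel))
    xs = np.arange(out_ncol) * pixel
    ys = np.arange(out_nrow) * pixel
    X, Y = np.meshgrid(xs, ys)
    grid_xy = np.column_stack([X.ravel(), Y.ravel()])

    zs = [p.z_mm for p in photos]
    dz = float(np.mean(np.diff(zs))) if len(zs) > 1 else 1.0
    if len(zs) > 1 and dz <= 0:
        raise ValueError("photo z locations must increase")

    voxels = np.zeros((out_ncol, out_nrow, len(photos)))
    for k, photo in enumerate(photos):
        src_xy = accumulated[k].inverse().apply(grid_xy)
        cols = src_xy[:, 0] / photo.pixel_size_mm
        rows = src_xy[:, 1] / photo.pixel_size_mm
        img = photo.pixels
        if img.ndim == 3:  # luminance of RGB photos
            img = img.mean(axis=2)
        sampled = map_coordinates(
            img.astype(float), np.vstack([rows, cols]), order=1, cval=0.0
        )
        voxels[:, :, k] = sampled.reshape(out_nrow, out_ncol).T
    volume = VolumeImage(voxels, (pixel, pixel, dz), (0.0, 0.0, float(zs[0])))
    return volume, accumulated
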