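"""Volume resampling through a point transform."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from ..imaging_io import VolumeImage

__all__ = ["resample_volume"]


def resample_volume(
    volume: VolumeImage,
    transform,
    target_grid: VolumeImage | tuple,
    *,
    fill_value: float = 0.0,
) -> VolumeImage:
    """Resample ``volume`` onto ``target_grid`` through ``transform``.

    ``transform`` maps *target* world coordinates into the *source*
    volume's world domain (i.e. pass the inverse of a forward
    source-to-target mapping).  It may be an in-plane 2D transform
    (applied per slice, z unchanged) or a callable taking and returning
    ``(n, 3)`` world coordinates.  Intensities are linearly interpolated;
    out-of-domain voxels get ``fill_value``.

    ``target_grid`` is either a template :class:`VolumeImage` (its voxel
    data is ignored) or a ``(shape, spacing_mm, origin_mm)`` tuple.
    """
    if isinstance(target_grid, VolumeImage):
        shape, spacing, origin = target_grid.shape, target_grid.spacing_mm, target_grid.origin_mm
    else:
        shape, spacing, origin = target_grid
    shape = tuple(int(s) for s in shape)

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    world = np.column_stack(
        [
            origin[0] + ii.ravel() * spacing[0],
            origin[1] + jj.ravel() * spacing[1],
            origin[2] + kk.ravel() * spacing[2],
        ]
    )
    mapped = _apply_transform_3d(transform, world)
    src_idx = (mapped - np.asarray(volume.origin_mm)) / np.asarray(volume.spacing_mm)
    sampled = map_coordinates(
        np.asarray(volume.voxels, dtype=float),
        src_idx.T,
        order=1,
        mode="constant",
        cval=fill_value,
    )
    return VolumeImage(sampled.reshape(shape), spacing, origin)


def _apply_transform_3d(transform, world: np.ndarray) -> np.ndarray:
    if transform is None:
        return world
    if hasattr(transform, "apply"):
        try:  # in-plane transform: act on (x, y), keep z
            xy = transform.apply(world[:, :2])
            return np.column_stack([xy, world[:, 2]])
        except (ValueError, IndexError):
            pass
    out = np.asarray(transform(world), dtype=float)
    if out.shape != world.shape:
        raise ValueError("transform must map (n, 3) world points to (n, 3)")
    return out
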