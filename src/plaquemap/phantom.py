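"""Synthetic single-lumen specimens with known ground truth.

A phantom is a straight (optionally drifting) tube cut into 1 mm
sections.  Its lumen surface carries the WSS field

    ``wss(theta, z) = baseline + gradient * z + amplitude * cos(theta)``

with ``theta`` the in-plane angle about the tube axis.  The en-face
photo stack is the shared domain; the in vivo / ex vivo / histology
modalities are the en-face geometry deformed by known similarity and
B-spline perturbations, so every registration stage can be checked
against ground truth.  Landmark pairs are similarity-consistent (the
B-spline perturbation acts on contours, mirroring the residual
non-rigid deformation that the landmark fit cannot absorb).

``truth_bin_values`` holds the per-bin mean WSS obtained by evaluating
the field formula on the lumen-surface vertex grid per angular wedge
and axial window — the closed-form sector/window average up to the
stated mesh discretisation, and bit-identical to what a perfect
(zero-deformation) pipeline run pools from the same vertices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _geometry as geom
from .imaging_io import (
    Contour,
    ContourStack,
    PlanarImage,
    SurfaceScalarField,
    VolumeImage,
    write_contours,
    write_planar_image,
    write_surface,
)
from .registration.transforms import (
    BSplineTransform2D,
    SimilarityTransform2D,
    TransformChain,
    transform_to_dict,
)

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "rasterize_contours_to_volume",
    "write_bundle",
    "read_bundle",
]

LANDMARK_RADIUS_EXTRA_MM = 1.5  # ref-slice landmark ring sits this far outside the lumen
PHOTO_EXTENT_MM = 16.0
PHOTO_PIXEL_MM = 0.1
PIN_OFFSETS = ((-6.0, -6.0), (6.0, -6.0), (6.0, 6.0), (-6.0, 6.0))


def _as_profile(value) -> Callable[[np.ndarray], np.ndarray]:
    if callable(value):
        return value
    scalar = float(value)
    return lambda z: np.full_like(np.asarray(z, dtype=float), scalar)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic specimen.

    ``lumen_radius_profile`` and ``wall_thickness_profile`` accept either
    a scalar (mm) or a callable of z (mm).  ``deformation_magnitude_mm``
    bounds the total modality-to-en-face displacement (similarity and
    B-spline perturbations each contribute at most half of it).
    ``thickness_circ_amplitude_mm`` makes the wall thickness vary as
    ``-cos(theta)`` around the circumference (anti-phase with the WSS
    circumferential term), which constructs a negative WSS-thickness
    correlation for sensitivity testing.
    """

    n_sections: int
    section_spacing_mm: float = 1.0
    lumen_radius_profile: object = 3.0
    wall_thickness_profile: object = 1.0
    wss_axial_gradient_pa_per_mm: float = 0.0
    wss_circumferential_amplitude_pa: float = 0.0
    wss_baseline_pa: float = 2.0
    deformation_magnitude_mm: float = 0.0
    rng_seed: int = 0
    # geometry / discretisation knobs
    axis_center_mm: tuple[float, float] = (8.0, 8.0)
    axis_drift_per_mm: tuple[float, float] = (0.0, 0.0)
    thickness_circ_amplitude_mm: float = 0.0
    reference_slice_index: int | None = None  # "bifurcation" anchor; default mid-stack
    n_theta: int = 256
    mesh_dz_mm: float = 0.1
    n_contour_points: int = 128
    axial_halfwidth_mm: float = 0.3
    n_bins: int = 8

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("invalid spec: n_sections must be >= 2")
        if self.section_spacing_mm <= 0:
            raise ValueError("invalid spec: section_spacing_mm must be > 0")
        if self.wss_baseline_pa <= 0:
            raise ValueError("invalid spec: wss_baseline_pa must be > 0")
        if self.wss_baseline_pa - abs(self.wss_circumferential_amplitude_pa) < 0:
            raise ValueError(
                "invalid spec: baseline - |circumferential amplitude| must be >= 0 "
                "(WSS magnitude non-negative)"
            )
        if self.deformation_magnitude_mm < 0:
            raise ValueError("invalid spec: deformation_magnitude_mm must be >= 0")
        zs = self.section_z()
        if np.any(self.lumen_radius(zs) <= 0):
            raise ValueError(
                "invalid spec: lumen_radius_profile(z) must be > 0 for all z in range"
            )
        if self.reference_slice_index is None:
            self.reference_slice_index = self.n_sections // 2

    def section_z(self) -> np.ndarray:
        return np.arange(self.n_sections) * self.section_spacing_mm

    def lumen_radius(self, z) -> np.ndarray:
        return np.asarray(_as_profile(self.lumen_radius_profile)(np.asarray(z, dtype=float)))

    def wall_thickness(self, z) -> np.ndarray:
        return np.asarray(_as_profile(self.wall_thickness_profile)(np.asarray(z, dtype=float)))

    def axis_at(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        return np.column_stack(
            [
                self.axis_center_mm[0] + self.axis_drift_per_mm[0] * z,
                self.axis_center_mm[1] + self.axis_drift_per_mm[1] * z,
            ]
        )

    def wss(self, theta, z) -> np.ndarray:
        return (
            self.wss_baseline_pa
            + self.wss_axial_gradient_pa_per_mm * np.asarray(z, dtype=float)
            + self.wss_circumferential_amplitude_pa * np.cos(np.asarray(theta, dtype=float))
        )


@dataclass
class PhantomBundle:
    """Everything a pipeline run needs, plus the generating ground truth."""

    spec: PhantomSpec
    enface_photos: list[PlanarImage]
    enface_contours: ContourStack
    histology_contours: ContourStack
    invivo_contours: ContourStack
    exvivo_contours: ContourStack
    wss_surface: SurfaceScalarField  # in the in vivo frame
    landmark_pairs: pd.DataFrame  # step, slice_index, label, fixed/moving x/y
    truth_transforms: dict[str, object]
    truth_bin_values: pd.DataFrame
    truth_photo_transforms: list[SimilarityTransform2D]

    def landmark_points(self, step: str, slice_index: int | None = None):
        grp = self.landmark_pairs[self.landmark_pairs["step"] == step]
        if slice_index is not None:
            grp = grp[grp["slice_index"] == slice_index]
        if len(grp) == 0:
            raise KeyError(f"no landmark pairs for step {step!r}")
        grp = grp.sort_values("label")
        fixed = grp[["fixed_x_mm", "fixed_y_mm"]].to_numpy()
        moving = grp[["moving_x_mm", "moving_y_mm"]].to_numpy()
        return fixed, moving


def _circle_about_axis(spec: PhantomSpec, z: float, radius_fn) -> np.ndarray:
    th = (np.arange(spec.n_contour_points) + 0.5) * 2 * np.pi / spec.n_contour_points
    r = radius_fn(th)
    ax = spec.axis_at(z)[0]
    return np.column_stack([ax[0] + r * np.cos(th), ax[1] + r * np.sin(th)])


def _draw_similarity(rng: np.random.Generator, d: float) -> SimilarityTransform2D:
    if d == 0:
        return SimilarityTransform2D()
    r_ref = 8.0  # displacement lever arm of the specimen cross-section
    rot = rng.uniform(-1, 1) * np.rad2deg(d / (2 * r_ref))
    scale = 1.0 + rng.uniform(-1, 1) * d / (4 * r_ref)
    trans = rng.uniform(-1, 1, 2) * d / (2 * np.sqrt(2))
    return SimilarityTransform2D(rot, scale, tuple(trans))


def _draw_bspline(
    rng: np.random.Generator, d: float, lo: np.ndarray, hi: np.ndarray
) -> BSplineTransform2D:
    """Truth warp on a coarse 4x4 control grid, displacements in [-d/2, d/2]."""
    width = float(max(hi[0] - lo[0], hi[1] - lo[1])) + 1.0
    origin = (lo[0] - width, lo[1] - width)
    coeff = (
        rng.uniform(-1, 1, (4, 4, 2)) * d / 2.0
        if d > 0
        else np.zeros((4, 4, 2))
    )
    return BSplineTransform2D(origin, (width, width), coeff)


def _invert_chain_points(points: np.ndarray, chain: TransformChain) -> np.ndarray:
    pts = points
    for transform, _, _ in reversed(chain.steps):
        if isinstance(transform, SimilarityTransform2D):
            pts = transform.inverse().apply(pts)
        elif isinstance(transform, BSplineTransform2D):
            pts = transform.invert_points(pts)
        else:  # pragma: no cover - chain holds only these two types
            raise TypeError(f"cannot invert {type(transform).__name__}")
    return pts


def generate_phantom(
    spec: PhantomSpec,
    *,
    similarity_overrides: dict[str, SimilarityTransform2D] | None = None,
    bspline_overrides: dict[str, BSplineTransform2D] | None = None,
) -> PhantomBundle:
    """Build a full synthetic specimen; deterministic for a fixed seed.

    ``similarity_overrides`` / ``bspline_overrides`` pin the truth
    deformation of a registration step ("A": in vivo to ex vivo, "B":
    ex vivo to en face, "C": histology to en face; B-splines only for
    A/B) instead of drawing it from the seeded RNG — used for
    parameter-recovery tests with prescribed transforms.
    """
    rng = np.random.default_rng(spec.rng_seed)
    d = spec.deformation_magnitude_mm
    similarity_overrides = similarity_overrides or {}
    bspline_overrides = bspline_overrides or {}

    zs = spec.section_z()
    radii = spec.lumen_radius(zs)
    thick = spec.wall_thickness(zs)

    # --- en-face domain geometry -------------------------------------------
    enface_entries = []
    histology_enface_entries = []
    mri_enface_entries = []
    for k, z in enumerate(zs):
        r, t = radii[k], thick[k]
        lumen = _circle_about_axis(spec, z, lambda th, r=r: np.full_like(th, r))
        media = _circle_about_axis(
            spec,
            z,
            lambda th, r=r, t=t: r + t - spec.thickness_circ_amplitude_mm * np.cos(th),
        )
        intima = _circle_about_axis(
            spec,
            z,
            lambda th, r=r, t=t: r
            + 0.5 * (t - spec.thickness_circ_amplitude_mm * np.cos(th)),
        )
        outer = _circle_about_axis(spec, z, lambda th, r=r, t=t: np.full_like(th, r + t))
        enface_entries.append(Contour(k, z, "lumen", lumen))
        histology_enface_entries.append(Contour(k, z, "lumen", lumen))
        histology_enface_entries.append(Contour(k, z, "intima", intima))
        histology_enface_entries.append(Contour(k, z, "media", media))
        mri_enface_entries.append(Contour(k, z, "lumen", lumen))
        mri_enface_entries.append(Contour(k, z, "outer_wall", outer))
    enface_contours = ContourStack(enface_entries)

    all_xy = np.vstack([c.points for c in mri_enface_entries])
    lo, hi = all_xy.min(axis=0), all_xy.max(axis=0)

    # --- truth transforms ---------------------------------------------------
    sim_A = similarity_overrides.get("A", _draw_similarity(rng, d))
    bsp_A = bspline_overrides.get("A", _draw_bspline(rng, d, lo, hi))
    sim_B = similarity_overrides.get("B", _draw_similarity(rng, d))
    bsp_B = bspline_overrides.get("B", _draw_bspline(rng, d, lo, hi))
    sim_C = similarity_overrides.get("C", _draw_similarity(rng, d))

    chain_invivo = TransformChain(
        [
            (sim_A, "invivo", "invivo_rigid"),
            (bsp_A, "invivo_rigid", "exvivo"),
            (sim_B, "exvivo", "exvivo_rigid"),
            (bsp_B, "exvivo_rigid", "enface"),
        ]
    )
    chain_exvivo = TransformChain(
        [(sim_B, "exvivo", "exvivo_rigid"), (bsp_B, "exvivo_rigid", "enface")]
    )
    chain_histology = TransformChain([(sim_C, "histology", "enface")])

    exvivo_contours = ContourStack(
        [
            Contour(
                c.slice_index,
                c.z_mm,
                c.structure,
                _invert_chain_points(c.points, chain_exvivo),
            )
            for c in mri_enface_entries
        ]
    )
    invivo_contours = ContourStack(
        [
            Contour(
                c.slice_index,
                c.z_mm,
                c.structure,
                _invert_chain_points(c.points, chain_invivo),
            )
            for c in mri_enface_entries
        ]
    )
    histology_contours = ContourStack(
        [
            Contour(
                c.slice_index,
                c.z_mm,
                c.structure,
                _invert_chain_points(c.points, chain_histology),
            )
            for c in histology_enface_entries
        ]
    )

    # --- WSS surface mesh in the in vivo frame ------------------------------
    # margin covers the default +-0.6 mm relocation sweep so edge-section
    # windows stay fully on the mesh
    margin = spec.axial_halfwidth_mm + 0.6
    # integer lattice keeps window membership symmetric about each section
    k0 = int(np.round((zs[0] - margin) / spec.mesh_dz_mm))
    k1 = int(np.round((zs[-1] + margin) / spec.mesh_dz_mm))
    mesh_z = np.arange(k0, k1 + 1) * spec.mesh_dz_mm
    theta = (np.arange(spec.n_theta) + 0.5) * 2 * np.pi / spec.n_theta
    TH, ZZ = np.meshgrid(theta, mesh_z)
    r_mesh = spec.lumen_radius(ZZ.ravel()).reshape(ZZ.shape)
    axis_xy = spec.axis_at(mesh_z)
    X = axis_xy[:, 0][:, None] + r_mesh * np.cos(TH)
    Y = axis_xy[:, 1][:, None] + r_mesh * np.sin(TH)
    scalar = spec.wss(TH.ravel(), ZZ.ravel())
    vertices_enface = np.column_stack([X.ravel(), Y.ravel(), ZZ.ravel()])
    nz, nt = len(mesh_z), spec.n_theta
    faces = []
    for i in range(nz - 1):
        j = np.arange(nt)
        jn = (j + 1) % nt
        a = i * nt + j
        b = i * nt + jn
        c = (i + 1) * nt + j
        e = (i + 1) * nt + jn
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([b, e, c]))
    faces = np.vstack(faces) if faces else np.zeros((0, 3), dtype=np.int64)
    xy_invivo = _invert_chain_points(vertices_enface[:, :2], chain_invivo)
    wss_surface = SurfaceScalarField(
        np.column_stack([xy_invivo, vertices_enface[:, 2]]), faces, scalar
    )

    # --- truth per-bin means ------------------------------------------------
    bins_of_theta = np.floor(spec.n_bins * theta / (2 * np.pi)).astype(int)
    truth_rows = []
    hw = spec.axial_halfwidth_mm * (1 + 1e-9)
    for k, z0 in enumerate(zs):
        in_window = np.abs(mesh_z - z0) <= hw
        zbar = float(mesh_z[in_window].mean())
        for b in range(spec.n_bins):
            sel = bins_of_theta == b
            mean_cos = float(np.cos(theta[sel]).mean())
            truth_rows.append(
                {
                    "slice_index": k,
                    "z_mm": z0,
                    "bin_index": b,
                    "mean_wss_pa": spec.wss_baseline_pa
                    + spec.wss_axial_gradient_pa_per_mm * zbar
                    + spec.wss_circumferential_amplitude_pa * mean_cos,
                }
            )
    truth_bin_values = pd.DataFrame(truth_rows)

    # --- landmark pairs -----------------------------------------------------
    z_ref = float(zs[spec.reference_slice_index])
    ax_ref = spec.axis_at(z_ref)[0]
    r_land = float(spec.lumen_radius(z_ref) + spec.wall_thickness(z_ref)) + LANDMARK_RADIUS_EXTRA_MM
    ang = np.deg2rad([20.0, 110.0, 200.0, 290.0])
    ref_points = np.column_stack(
        [ax_ref[0] + r_land * np.cos(ang), ax_ref[1] + r_land * np.sin(ang)]
    )
    pair_rows = []
    # step B: ex vivo <-> en face; step A: in vivo <-> ex vivo
    l_ex = sim_B.inverse().apply(ref_points)
    l_inv = sim_A.inverse().apply(l_ex)
    for label, f, m in zip("PQRS", ref_points, l_ex):
        pair_rows.append(("B", spec.reference_slice_index, label, f[0], f[1], m[0], m[1]))
    for label, f, m in zip("PQRS", l_ex, l_inv):
        pair_rows.append(("A", spec.reference_slice_index, label, f[0], f[1], m[0], m[1]))
    # step C: per-section histology <-> en face
    for k, z in enumerate(zs):
        axk = spec.axis_at(z)[0]
        rk = float(spec.lumen_radius(z) + spec.wall_thickness(z)) + LANDMARK_RADIUS_EXTRA_MM
        pts = np.column_stack([axk[0] + rk * np.cos(ang), axk[1] + rk * np.sin(ang)])
        moved = sim_C.inverse().apply(pts)
        for label, f, m in zip("PQRS", pts, moved):
            pair_rows.append(("C", k, label, f[0], f[1], m[0], m[1]))
    landmark_pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "step",
            "slice_index",
            "label",
            "fixed_x_mm",
            "fixed_y_mm",
            "moving_x_mm",
            "moving_y_mm",
        ],
    )

    # --- en-face photos with pin landmarks ---------------------------------
    photos = []
    photo_transforms = []
    center = np.array([PHOTO_EXTENT_MM / 2, PHOTO_EXTENT_MM / 2])
    pins = np.asarray(PIN_OFFSETS) + np.asarray(spec.axis_center_mm)
    npx = int(round(PHOTO_EXTENT_MM / PHOTO_PIXEL_MM))
    cols = (np.arange(npx) + 0.0) * PHOTO_PIXEL_MM
    Xp, Yp = np.meshgrid(cols, cols)
    grid = np.column_stack([Xp.ravel(), Yp.ravel()])
    for k, z in enumerate(zs):
        if k == 0 or d == 0:
            m_k = SimilarityTransform2D()
        else:
            rot = rng.uniform(-1, 1) * 10.0 * min(d, 1.0)
            trans = rng.uniform(-1, 1, 2) * d / 2.0
            th = np.deg2rad(rot)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            t = center - R @ center + trans  # rotate about the photo centre
            m_k = SimilarityTransform2D(rot, 1.0, tuple(t))
        photo_transforms.append(m_k.inverse())  # photo k frame -> en-face frame

        world = m_k.inverse().apply(grid)
        axz = spec.axis_at(z)[0]
        rr = np.hypot(world[:, 0] - axz[0], world[:, 1] - axz[1])
        img = np.full(rr.shape, 10, dtype=np.uint8)
        img[rr <= radii[k] + thick[k]] = 200
        img[rr <= radii[k]] = 50
        pin_photo = m_k.apply(pins)
        landmarks = {f"L{i + 1}": (p[0], p[1]) for i, p in enumerate(pin_photo)}
        photos.append(
            PlanarImage(img.reshape(npx, npx), PHOTO_PIXEL_MM, z, landmarks)
        )

    truth_transforms = {
        "invivo": chain_invivo,
        "exvivo": chain_exvivo,
        "histology": chain_histology,
    }
    return PhantomBundle(
        spec=spec,
        enface_photos=photos,
        enface_contours=enface_contours,
        histology_contours=histology_contours,
        invivo_contours=invivo_contours,
        exvivo_contours=exvivo_contours,
        wss_surface=wss_surface,
        landmark_pairs=landmark_pairs,
        truth_transforms=truth_transforms,
        truth_bin_values=truth_bin_values,
        truth_photo_transforms=photo_transforms,
    )


def rasterize_contours_to_volume(
    contours: ContourStack,
    spacing: Sequence[float],
    *,
    origin_mm: Sequence[float] | None = None,
    shape: Sequence[int] | None = None,
) -> VolumeImage:
    """Binary occupancy volume of a contour stack.

    A voxel is 1 when its centre lies inside a contour polygon assigned
    to its z plane; each contour fills the nearest plane, and only if it
    is strictly closer than half the z spacing (a contour exactly
    between two planes fills neither).

    Raises
    ------
    ValueError
        On an empty stack or non-positive spacing (self-intersecting
        contours are rejected at :class:`Contour` construction).
    """
    if len(contours) == 0:
        raise ValueError("cannot rasterize an empty contour stack")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be strictly positive")

    pts = np.vstack([c.points for c in contours])
    zvals = np.array([c.z_mm for c in contours])
    if origin_mm is None:
        origin_mm = (
            pts[:, 0].min() - spacing[0],
            pts[:, 1].min() - spacing[1],
            zvals.min(),
        )
    origin_mm = tuple(float(v) for v in origin_mm)
    if shape is None:
        shape = (
            int(np.ceil((pts[:, 0].max() - origin_mm[0]) / spacing[0])) + 2,
            int(np.ceil((pts[:, 1].max() - origin_mm[1]) / spacing[1])) + 2,
            int(np.ceil((zvals.max() - origin_mm[2]) / spacing[2])) + 1,
        )
    shape = tuple(int(s) for s in shape)

    voxels = np.zeros(shape)
    xs = origin_mm[0] + np.arange(shape[0]) * spacing[0]
    ys = origin_mm[1] + np.arange(shape[1]) * spacing[1]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for c in contours:
        k = (c.z_mm - origin_mm[2]) / spacing[2]
        k_near = int(np.rint(k))
        if k_near < 0 or k_near >= shape[2]:
            continue
        if abs(k - k_near) * spacing[2] >= spacing[2] / 2 - 1e-12:
            continue  # strictly between planes: fills neither
        inside = geom.contains_xy(c.points, X.ravel(), Y.ravel()).reshape(X.shape)
        voxels[:, :, k_near] = np.maximum(voxels[:, :, k_near], inside.astype(float))
    return VolumeImage(voxels, spacing, origin_mm)


# ---------------------------------------------------------------------------
# bundle directory I/O
# ---------------------------------------------------------------------------


def write_bundle(bundle: PhantomBundle, directory) -> Path:
    """Write a specimen directory (photos, contour/landmark CSVs, surface,
    truth transforms JSON, truth bin table)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, photo in enumerate(bundle.enface_photos):
        write_planar_image(photo, directory / f"enface_{k:03d}.png")
    write_contours(bundle.enface_contours, directory / "enface_contours.csv")
    write_contours(bundle.histology_contours, directory / "histology_contours.csv")
    write_contours(bundle.invivo_contours, directory / "invivo_contours.csv")
    write_contours(bundle.exvivo_contours, directory / "exvivo_contours.csv")
    write_surface(bundle.wss_surface, directory / "wss_surface.vtp")
    bundle.landmark_pairs.to_csv(
        directory / "landmark_pairs.csv", index=False, float_format="%.12g"
    )
    bundle.truth_bin_values.to_csv(
        directory / "truth_bin_values.csv", index=False, float_format="%.12g"
    )
    truth = {name: transform_to_dict(t) for name, t in bundle.truth_transforms.items()}
    truth["enface_photos"] = [
        transform_to_dict(t) for t in bundle.truth_photo_transforms
    ]
    (directory / "truth_transforms.json").write_text(json.dumps(truth, indent=1))
    meta = {
        "n_sections": bundle.spec.n_sections,
        "section_spacing_mm": bundle.spec.section_spacing_mm,
        "reference_slice_index": bundle.spec.reference_slice_index,
        "rng_seed": bundle.spec.rng_seed,
        "n_bins": bundle.spec.n_bins,
        "axial_halfwidth_mm": bundle.spec.axial_halfwidth_mm,
    }
    (directory / "specimen.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_bundle(directory) -> dict:
    """Read a specimen directory into plain pipeline inputs (no truth)."""
    from .imaging_io import read_contours, read_planar_image, read_surface

    directory = Path(directory)
    meta = json.loads((directory / "specimen.json").read_text())
    photos = [
        read_planar_image(p) for p in sorted(directory.glob("enface_*.png"))
    ]
    return {
        "meta": meta,
        "enface_photos": photos,
        "enface_contours": read_contours(directory / "enface_contours.csv"),
        "histology_contours": read_contours(directory / "histology_contours.csv"),
        "invivo_contours": read_contours(directory / "invivo_contours.csv"),
        "exvivo_contours": read_contours(directory / "exvivo_contours.csv"),
        "wss_surface": read_surface(directory / "wss_surface.vtp"),
        "landmark_pairs": pd.read_csv(directory / "landmark_pairs.csv"),
    }
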