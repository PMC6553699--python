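"""Data types and on-disk formats shared by the whole pipeline.

Coordinate conventions
----------------------
* All world coordinates are millimetres in a right-handed frame.
* The z axis is the specimen's axial direction, increasing caudal to
  cranial; slice planes are orthogonal to z.
* Section / en-face z equals ``slice_index * section_spacing`` (nominal
  1 mm sectioning); an en-face photo represents the proximal face of its
  section, so the photo's z is the proximal-face z.
* ``VolumeImage`` voxel ``(i, j, k)`` sits at
  ``origin + (i, j, k) * spacing`` with 0-based indices; axis 0 is x,
  axis 1 is y, axis 2 is z.
* Contours are stored as ordered open vertex lists, counter-clockwise
  when viewed from +z; orientation is enforced by reorientation on read,
  never by rejection.

Formats
-------
Volumes: NIfTI (``.nii``/``.nii.gz``) and MetaImage (``.mhd`` + ``.raw``).
Photos: PNG/TIFF plus a JSON sidecar carrying pixel size, z and landmarks.
Contours, landmarks and bin tables: UTF-8 CSV with a header row.
Surfaces: VTK PolyData XML (``.vtp``, ascii) and PLY (ascii), both with a
per-vertex scalar array named ``wss_pa``.  Transforms: JSON (see
:mod:`plaquemap.registration.transforms`).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _geometry as geom

__all__ = [
    "STRUCTURES",
    "VolumeImage",
    "PlanarImage",
    "Contour",
    "ContourStack",
    "SurfaceScalarField",
    "read_volume",
    "write_volume",
    "read_planar_image",
    "write_planar_image",
    "read_contours",
    "write_contours",
    "read_landmarks",
    "write_landmarks",
    "read_surface",
    "write_surface",
    "read_bin_table",
    "write_bin_table",
]

#: Anatomical structures a contour may delineate.
STRUCTURES = ("lumen", "outer_wall", "intima", "media")

BIN_TABLE_COLUMNS = [
    "specimen_id",
    "slice_index",
    "z_mm",
    "bin_index",
    "mean_wss_pa",
    "min_wss_pa",
    "max_wss_pa",
    "plaque_thickness_mm",
    "error_flags",
    "included",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VolumeImage:
    """Regular 3D scalar grid with physical spacing and origin."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return np.asarray(self.origin_mm) + ijk * np.asarray(self.spacing_mm)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return (xyz - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


@dataclass
class PlanarImage:
    """2D photo with calibrated pixel size, axial location and landmarks.

    ``landmarks`` maps a unique label to an (x, y) position in mm; pixel
    ``(row, col)`` has its centre at ``(col * pixel_size_mm,
    row * pixel_size_mm)``.
    """

    pixels: np.ndarray
    pixel_size_mm: float
    z_mm: float
    landmarks: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D grayscale or 3D RGB")
        self.pixel_size_mm = float(self.pixel_size_mm)
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be > 0")
        self.z_mm = float(self.z_mm)
        self.landmarks = {
            str(k): (float(v[0]), float(v[1])) for k, v in self.landmarks.items()
        }

    def landmark_array(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.landmarks[l] for l in labels], dtype=float)


@dataclass
class Contour:
    """One closed planar polyline of a structure on one section."""

    slice_index: int
    z_mm: float
    structure: str
    points: np.ndarray

    def __post_init__(self) -> None:
        self.slice_index = int(self.slice_index)
        self.z_mm = float(self.z_mm)
        self.structure = str(self.structure)
        pts = geom.dedup_closed(geom.as_points(self.points))
        if len(np.unique(np.round(pts, 12), axis=0)) < 3:
            raise ValueError(
                f"contour (slice {self.slice_index}, {self.structure}) needs "
                "at least 3 distinct vertices"
            )
        if not geom.is_simple_contour(pts):
            raise ValueError(
                f"contour (slice {self.slice_index}, {self.structure}) is "
                "not a simple closed polyline"
            )
        self.points = geom.ensure_ccw(pts)

    def polygon(self):
        return geom.contour_polygon(self.points)


class ContourStack:
    """Ordered closed contours at known z locations, keyed by
    ``(slice_index, structure)``."""

    def __init__(self, entries: Iterable[Contour]):
        self.entries: list[Contour] = sorted(
            entries, key=lambda c: (c.slice_index, c.structure)
        )
        self._validate()

    def _validate(self) -> None:
        seen: dict[tuple[int, str], float] = {}
        for c in self.entries:
            key = (c.slice_index, c.structure)
            if key in seen:
                raise ValueError(f"duplicate contour for slice {key[0]} / {key[1]}")
            seen[key] = c.z_mm
        for structure in {c.structure for c in self.entries}:
            zs = [c.z_mm for c in self.entries if c.structure == structure]
            idx = [c.slice_index for c in self.entries if c.structure == structure]
            order = np.argsort(idx)
            zs_sorted = np.asarray(zs)[order]
            if np.any(np.diff(zs_sorted) <= 0):
                raise ValueError(
                    f"z_mm must increase strictly with slice_index ({structure})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def structures(self) -> list[str]:
        return sorted({c.structure for c in self.entries})

    def slice_indices(self, structure: str | None = None) -> list[int]:
        return sorted(
            {
                c.slice_index
                for c in self.entries
                if structure is None or c.structure == structure
            }
        )

    def get(self, slice_index: int, structure: str) -> Contour:
        for c in self.entries:
            if c.slice_index == slice_index and c.structure == structure:
                return c
        raise KeyError(f"no contour for slice {slice_index} / {structure}")

    def has(self, slice_index: int, structure: str) -> bool:
        return any(
            c.slice_index == slice_index and c.structure == structure
            for c in self.entries
        )

    def select(self, structure: str) -> "ContourStack":
        return ContourStack([c for c in self.entries if c.structure == structure])

    def map_points(self, fn) -> "ContourStack":
        """Apply an in-plane point mapping ``fn((n,2)) -> (n,2)`` to every
        contour, preserving slice indices and z."""
        return ContourStack(
            [
                Contour(c.slice_index, c.z_mm, c.structure, fn(c.points))
                for c in self.entries
            ]
        )


@dataclass
class SurfaceScalarField:
    """Triangulated lumen surface carrying one WSS scalar (Pa) per vertex."""

    vertices: np.ndarray
    faces: np.ndarray
    scalar: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.scalar = np.asarray(self.scalar, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise ValueError("faces must be (m, 3) triangles")
        if self.scalar.shape != (len(self.vertices),):
            raise ValueError("exactly one scalar per vertex required")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if np.any(self.scalar < 0):
            raise ValueError("WSS scalar must be non-negative")

    def translated_z(self, dz_mm: float) -> "SurfaceScalarField":
        v = self.vertices.copy()
        v[:, 2] += dz_mm
        return SurfaceScalarField(v, self.faces.copy(), self.scalar.copy())


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def write_volume(volume: VolumeImage, path) -> None:
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing_mm) + [1.0])
        affine[:3, 3] = volume.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float64), affine), path)
    elif path.suffix == ".mhd":
        _write_metaimage(volume, path)
    else:
        raise ValueError(f"unknown volume format: {path.name!r}")


def read_volume(path) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
        return VolumeImage(np.asarray(img.dataobj, dtype=float), spacing, origin)
    if path.suffix == ".mhd":
        return _read_metaimage(path)
    raise ValueError(f"unknown volume format: {path.name!r}")


_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


def _write_metaimage(volume: VolumeImage, path: Path) -> None:
    raw_name = path.with_suffix(".raw").name
    nx, ny, nz = volume.shape
    header = "\n".join(
        [
            "ObjectType = Image",
            "NDims = 3",
            "BinaryData = True",
            "BinaryDataByteOrderMSB = False",
            f"DimSize = {nx} {ny} {nz}",
            "ElementType = MET_DOUBLE",
            f"ElementSpacing = {volume.spacing_mm[0]} {volume.spacing_mm[1]} {volume.spacing_mm[2]}",
            f"Offset = {volume.origin_mm[0]} {volume.origin_mm[1]} {volume.origin_mm[2]}",
            f"ElementDataFile = {raw_name}",
        ]
    )
    path.write_text(header + "\n")
    # MetaImage raw layout: x varies fastest
    data = np.asarray(volume.voxels, dtype=np.float64).flatten(order="F")
    path.with_suffix(".raw").write_bytes(data.tobytes())


def _read_metaimage(path: Path) -> VolumeImage:
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        dims = tuple(int(v) for v in fields["DimSize"].split())
        spacing = tuple(float(v) for v in fields["ElementSpacing"].split())
        origin = tuple(float(v) for v in fields.get("Offset", "0 0 0").split())
        dtype = _MET_TYPES[fields["ElementType"]]
        raw = path.parent / fields["ElementDataFile"]
    except KeyError as exc:
        raise ValueError(f"corrupt MetaImage header {path}: missing {exc}") from exc
    data = np.frombuffer(raw.read_bytes(), dtype=dtype)
    if data.size != int(np.prod(dims)):
        raise ValueError(f"corrupt MetaImage raw file for {path}")
    voxels = data.reshape(dims, order="F").astype(float)
    return VolumeImage(voxels, spacing, origin)


# ---------------------------------------------------------------------------
# planar images
# ---------------------------------------------------------------------------


def write_planar_image(image: PlanarImage, path) -> None:
    """Write the photo (PNG/TIFF) plus a ``<stem>.meta.json`` sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    pixels = image.pixels
    if pixels.dtype != np.uint8:
        lo, hi = float(pixels.min(initial=0)), float(pixels.max(initial=1))
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        pixels = np.clip((pixels - lo) * scale, 0, 255).astype(np.uint8)
    iio.imwrite(path, pixels)
    meta = {
        "pixel_size_mm": image.pixel_size_mm,
        "z_mm": image.z_mm,
        "landmarks": {k: list(v) for k, v in image.landmarks.items()},
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_planar_image(path) -> PlanarImage:
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"photo not found: {path}")
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path} for {path}")
    meta = json.loads(meta_path.read_text())
    pixels = iio.imread(path)
    return PlanarImage(
        pixels,
        meta["pixel_size_mm"],
        meta["z_mm"],
        {k: tuple(v) for k, v in meta["landmarks"].items()},
    )


# ---------------------------------------------------------------------------
# contours / landmarks
# ---------------------------------------------------------------------------

CONTOUR_COLUMNS = ["slice_index", "structure", "point_index", "x_mm", "y_mm", "z_mm"]


def write_contours(stack: ContourStack, path) -> None:
    rows = []
    for c in stack:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.slice_index, c.structure, i, x, y, c.z_mm))
    df = pd.DataFrame(rows, columns=CONTOUR_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_contours(path) -> ContourStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"contour table not found: {path}")
    df = pd.read_csv(path)
    missing = set(CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["slice_index", "structure", "point_index"]).any():
        raise ValueError(f"{path}: duplicate (slice_index, structure, point_index)")
    entries = []
    for (sl, structure), grp in df.groupby(["slice_index", "structure"], sort=True):
        grp = grp.sort_values("point_index")
        z = grp["z_mm"].to_numpy()
        if not np.allclose(z, z[0]):
            raise ValueError(
                f"{path}: contour slice {sl}/{structure} has inconsistent z_mm"
            )
        pts = grp[["x_mm", "y_mm"]].to_numpy()
        try:
            entries.append(Contour(int(sl), float(z[0]), str(structure), pts))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return ContourStack(entries)


def write_landmarks(landmarks: dict[int, dict[str, tuple[float, float]]], path) -> None:
    """Landmarks per slice: ``{slice_index: {label: (x_mm, y_mm)}}``."""
    rows = [
        (sl, label, xy[0], xy[1])
        for sl, marks in landmarks.items()
        for label, xy in marks.items()
    ]
    pd.DataFrame(rows, columns=["slice_index", "label", "x_mm", "y_mm"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_landmarks(path) -> dict[int, dict[str, tuple[float, float]]]:
    df = pd.read_csv(path)
    out: dict[int, dict[str, tuple[float, float]]] = {}
    for row in df.itertuples(index=False):
        marks = out.setdefault(int(row.slice_index), {})
        if row.label in marks:
            raise ValueError(f"duplicate landmark label {row.label!r} on slice {row.slice_index}")
        marks[str(row.label)] = (float(row.x_mm), float(row.y_mm))
    return out


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------


def write_surface(fieldobj: SurfaceScalarField, path) -> None:
    path = Path(path)
    if path.suffix == ".vtp":
        _write_vtp(fieldobj, path)
    elif path.suffix == ".ply":
        _write_ply(fieldobj, path)
    else:
        raise ValueError(f"unknown surface format: {path.name!r}")


def read_surface(path) -> SurfaceScalarField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"surface not found: {path}")
    if path.suffix == ".vtp":
        return _read_vtp(path)
    if path.suffix == ".ply":
        return _read_ply(path)
    raise ValueError(f"unknown surface format: {path.name!r}")


def _fmt_array(a: np.ndarray) -> str:
    return " ".join(repr(v) if isinstance(v, float) else str(v) for v in a.ravel().tolist())


def _write_vtp(f: SurfaceScalarField, path: Path) -> None:
    n_pts, n_polys = len(f.vertices), len(f.faces)
    conn = _fmt_array(f.faces)
    offsets = _fmt_array(np.arange(1, n_polys + 1) * 3)
    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
 <PolyData>
  <Piece NumberOfPoints="{n_pts}" NumberOfVerts="0" NumberOfLines="0" NumberOfStrips="0" NumberOfPolys="{n_polys}">
   <PointData Scalars="wss_pa">
    <DataArray type="Float64" Name="wss_pa" format="ascii">{_fmt_array(f.scalar)}</DataArray>
   </PointData>
   <Points>
    <DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt_array(f.vertices)}</DataArray>
   </Points>
   <Polys>
    <DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
    <DataArray type="Int64" Name="offsets" format="ascii">{offsets}</DataArray>
   </Polys>
  </Piece>
 </PolyData>
</VTKFile>
"""
    path.write_text(xml)


def _read_vtp(path: Path) -> SurfaceScalarField:
    root = ET.parse(path).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK PolyData file")
    arrays = {}
    for da in piece.iter("DataArray"):
        arrays[da.get("Name")] = da
    points_el = piece.find("./Points/DataArray")
    if points_el is None:
        raise ValueError(f"{path}: missing Points array")
    vertices = np.fromstring(points_el.text, sep=" ").reshape(-1, 3)
    scalar_el = piece.find("./PointData/DataArray[@Name='wss_pa']")
    if scalar_el is None:
        raise ValueError(f"{path}: missing required vertex scalar 'wss_pa'")
    scalar = np.fromstring(scalar_el.text, sep=" ")
    conn_el = piece.find("./Polys/DataArray[@Name='connectivity']")
    faces = (
        np.fromstring(conn_el.text, sep=" ").astype(np.int64).reshape(-1, 3)
        if conn_el is not None and conn_el.text and conn_el.text.strip()
        else np.zeros((0, 3), dtype=np.int64)
    )
    return SurfaceScalarField(vertices, faces, scalar)


def _write_ply(f: SurfaceScalarField, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(f.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        "property double wss_pa",
        f"element face {len(f.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, s in zip(f.vertices, f.scalar):
        lines.append(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r} {float(s)!r}")
    for face in f.faces:
        lines.append(f"3 {face[0]} {face[1]} {face[2]}")
    path.write_text("\n".join(lines) + "\n")


def _read_ply(path: Path) -> SurfaceScalarField:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    n_vertex = n_face = 0
    props: list[str] = []
    i = 1
    while i < len(lines):
        tok = lines[i].split()
        if tok[:2] == ["element", "vertex"]:
            n_vertex = int(tok[2])
            current = "vertex"
        elif tok[:2] == ["element", "face"]:
            n_face = int(tok[2])
            current = "face"
        elif tok[:1] == ["property"] and tok[1] != "list" and current == "vertex":
            props.append(tok[-1])
        elif tok == ["end_header"]:
            i += 1
            break
        i += 1
    if "wss_pa" not in props:
        raise ValueError(f"{path}: missing required vertex scalar 'wss_pa'")
    body = lines[i:]
    vdata = np.array([[float(v) for v in ln.split()] for ln in body[:n_vertex]])
    cols = {p: j for j, p in enumerate(props)}
    vertices = vdata[:, [cols["x"], cols["y"], cols["z"]]]
    scalar = vdata[:, cols["wss_pa"]]
    faces = np.array(
        [[int(v) for v in ln.split()[1:4]] for ln in body[n_vertex : n_vertex + n_face]],
        dtype=np.int64,
    ).reshape(-1, 3)
    return SurfaceScalarField(vertices, faces, scalar)


# ---------------------------------------------------------------------------
# bin tables
# ---------------------------------------------------------------------------


def write_bin_table(table: pd.DataFrame, path) -> None:
    missing = set(BIN_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"bin table missing columns {sorted(missing)}")
    table[BIN_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_bin_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bin table not found: {path}")
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = set(BIN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["error_flags"] = df["error_flags"].fillna("").astype(str)
    df["included"] = df["included"].astype(bool)
    if df.duplicated(subset=["specimen_id", "slice_index", "bin_index"]).any():
        raise ValueError(f"{path}: duplicate (specimen_id, slice_index, bin_index)")
    return df
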