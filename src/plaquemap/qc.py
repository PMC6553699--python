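"""Registration quality metrics and error-flag exclusion bookkeeping.

Error flags are inputs (consensus visual assessment), read from CSV with
columns ``specimen_id, slice_index, bin_index, error_type`` where
``error_type`` is one of ``type1`` (histology processing artefact),
``type2`` (histology / en-face mismatch) and ``type3`` (MRI / en-face
mismatch).  A bin flagged with any error is excluded from downstream
statistics; a multi-flag bin is excluded (and counted in remaining-bin
tallies) exactly once.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from . import _geometry as geom

__all__ = [
    "ERROR_TYPES",
    "dice_coefficient",
    "contour_to_mask",
    "hausdorff_distance",
    "read_flags",
    "write_flags",
    "apply_exclusions",
    "exclusion_tally",
    "qc_summary",
    "cross_specimen_mean",
]

ERROR_TYPES = ("type1", "type2", "type3")


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)`` of two binary masks.

    Both masks empty is defined as 1.0 (identical empty segmentations);
    exactly one empty mask is an error.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        raise ValueError("exactly one mask is empty; DSC undefined")
    return 2.0 * int((a & b).sum()) / (na + nb)


def contour_to_mask(
    contour_points, pixel_mm: float = 0.05, bounds=None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize a closed contour to a binary mask of pixel centres inside.

    Returns the mask (rows = y, cols = x) and the (x, y) world position
    of pixel (0, 0).  Pass a shared ``bounds = (xmin, ymin, xmax, ymax)``
    to put two contours on the same grid for DSC.
    """
    pts = geom.as_points(contour_points)
    if bounds is None:
        lo = pts.min(axis=0) - 2 * pixel_mm
        hi = pts.max(axis=0) + 2 * pixel_mm
        bounds = (lo[0], lo[1], hi[0], hi[1])
    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin, xmax + pixel_mm / 2, pixel_mm)
    ys = np.arange(ymin, ymax + pixel_mm / 2, pixel_mm)
    X, Y = np.meshgrid(xs, ys)
    mask = geom.contains_xy(pts, X.ravel(), Y.ravel()).reshape(len(ys), len(xs))
    return mask, (float(xmin), float(ymin))


def dice_between_contours(contour_a, contour_b, pixel_mm: float = 0.05) -> float:
    """DSC of two contours rasterized on a shared grid (default 0.05 mm/px)."""
    a = geom.as_points(contour_a)
    b = geom.as_points(contour_b)
    lo = np.minimum(a.min(axis=0), b.min(axis=0)) - 2 * pixel_mm
    hi = np.maximum(a.max(axis=0), b.max(axis=0)) + 2 * pixel_mm
    bounds = (lo[0], lo[1], hi[0], hi[1])
    mask_a, _ = contour_to_mask(a, pixel_mm, bounds)
    mask_b, _ = contour_to_mask(b, pixel_mm, bounds)
    return dice_coefficient(mask_a, mask_b)


def hausdorff_distance(
    contour_a, contour_b, *, resample_mm: float = 0.02
) -> float:
    """Symmetric Hausdorff distance (mm) between two closed contour curves.

    Both contours are densely resampled (arc spacing <= ``resample_mm``)
    and each direction takes the supremum over samples of the exact
    point-to-polyline distance, so the result is the continuous
    curve-to-curve Hausdorff distance up to the resampling tolerance.
    """
    a = geom.as_points(contour_a)
    b = geom.as_points(contour_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty contour")
    ring_a = geom.contour_linestring(a)
    ring_b = geom.contour_linestring(b)
    dense_a = geom.densify_contour(a, resample_mm)
    dense_b = geom.densify_contour(b, resample_mm)
    d_ab = max(ring_b.distance(Point(p)) for p in dense_a)
    d_ba = max(ring_a.distance(Point(p)) for p in dense_b)
    return float(max(d_ab, d_ba))


# ---------------------------------------------------------------------------
# exclusion bookkeeping
# ---------------------------------------------------------------------------

FLAG_COLUMNS = ["specimen_id", "slice_index", "bin_index", "error_type"]


def read_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FLAG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flags file missing columns {sorted(missing)}")
    bad = set(df["error_type"].unique()) - set(ERROR_TYPES)
    if bad:
        raise ValueError(f"unknown error types {sorted(bad)}; expected {ERROR_TYPES}")
    return df


def write_flags(flags: pd.DataFrame, path) -> None:
    flags[FLAG_COLUMNS].to_csv(path, index=False)


def apply_exclusions(table: pd.DataFrame, flags: pd.DataFrame) -> pd.DataFrame:
    """Mark flagged bins as excluded in a bin table.

    Sets ``included = False`` exactly for bins carrying at least one
    flag and records the sorted flag set in ``error_flags`` (joined with
    ``+``).  Bins with multiple flags are excluded once.

    Raises
    ------
    KeyError
        If a flag references a (specimen, slice, bin) absent from the table.
    """
    table = table.copy()
    key_cols = ["specimen_id", "slice_index", "bin_index"]
    table_keys = set(map(tuple, table[key_cols].itertuples(index=False, name=None)))
    flag_sets: dict[tuple, set] = {}
    for row in flags.itertuples(index=False):
        key = (row.specimen_id, int(row.slice_index), int(row.bin_index))
        if key not in table_keys:
            raise KeyError(f"flag references unknown bin {key}")
        flag_sets.setdefault(key, set()).add(row.error_type)
    joined = {k: "+".join(sorted(v)) for k, v in flag_sets.items()}
    keys = list(map(tuple, table[key_cols].itertuples(index=False, name=None)))
    table["error_flags"] = [joined.get(k, "") for k in keys]
    table["included"] = table["error_flags"] == ""
    return table


def exclusion_tally(table: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen exclusion counts: per-type tallies, union of excluded
    bins and the remaining-bin count/fraction.

    Multi-flag bins appear in each per-type tally but once in the union.
    """
    rows = []
    for specimen, grp in table.groupby("specimen_id", sort=True):
        n_total = len(grp)
        per_type = {
            t: int(grp["error_flags"].str.contains(t).sum()) for t in ERROR_TYPES
        }
        n_excluded = int((~grp["included"]).sum())
        rows.append(
            {
                "specimen_id": specimen,
                "n_bins": n_total,
                **{f"n_{t}": per_type[t] for t in ERROR_TYPES},
                "n_excluded": n_excluded,
                "n_remaining": n_total - n_excluded,
                "remaining_fraction": (n_total - n_excluded) / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


def cross_specimen_mean(values: Sequence[float], ndigits: int = 2) -> float:
    """Mean across specimens, reported at two decimals (half-up rounding)."""
    mean = float(np.mean(np.asarray(values, dtype=float)))
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mean)).quantize(q, rounding=ROUND_HALF_UP))


METRIC_COLUMNS = ["dsc_type2", "dsc_type3", "hd_type2_mm", "hd_type3_mm"]


def qc_summary(metrics: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-specimen and cross-specimen DSC/HD summary, before vs. after exclusion.

    ``metrics`` holds one row per section with columns ``specimen_id``,
    ``slice_index`` and any of ``dsc_type2``, ``dsc_type3``,
    ``hd_type2_mm``, ``hd_type3_mm``.  "Before" aggregates over all
    sections of a specimen.  "After" aggregates, per error type, only
    over sections none of whose bins carry that type's flag in ``table``
    (per-section averaging); with no bin table, after equals before.

    The returned frame has one row per specimen plus an ``average`` row
    holding the cross-specimen means rounded to two decimals.
    """
    present = [c for c in METRIC_COLUMNS if c in metrics.columns]
    if not present:
        raise ValueError(f"metrics frame has none of {METRIC_COLUMNS}")

    def flagged_slices(specimen: str, error_type: str) -> set[int]:
        if table is None:
            return set()
        grp = table[
            (table["specimen_id"] == specimen)
            & table["error_flags"].str.contains(error_type)
        ]
        return set(grp["slice_index"].astype(int))

    rows = []
    for specimen, grp in metrics.groupby("specimen_id", sort=True):
        row: dict = {"specimen_id": specimen}
        for col in present:
            error_type = "type2" if "type2" in col else "type3"
            row[f"{col}_before"] = float(grp[col].mean())
            keep = ~grp["slice_index"].astype(int).isin(flagged_slices(specimen, error_type))
            row[f"{col}_after"] = float(grp.loc[keep, col].mean()) if keep.any() else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)

    avg: dict = {"specimen_id": "average"}
    for col in out.columns:
        if col == "specimen_id":
            continue
        avg[col] = cross_specimen_mean(out[col].dropna().to_numpy())
    return pd.concat([out, pd.DataFrame([avg])], ignore_index=True)
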