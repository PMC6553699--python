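"""End-to-end pipeline: registration chain, projection, QC, sensitivity.

Stages can run individually (each reads its predecessors' outputs from
the run directory) or all at once via :func:`run_pipeline`.  Every run
writes a manifest recording the configuration hash, seed and package
versions, so a run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binning import ProjectionParams
from .centerline import compute_centerline
from .imaging_io import ContourStack, read_bin_table, write_bin_table, write_volume
from .phantom import read_bundle
from .qc import (
    apply_exclusions,
    dice_between_contours,
    exclusion_tally,
    hausdorff_distance,
    qc_summary,
    read_flags,
)
from .registration import (
    BSplineRegistrationParams,
    TransformChain,
    fit_similarity_from_landmarks,
    load_transform,
    register_contours_bspline,
    save_transform,
    stack_enface_photos,
    transform_from_dict,
    transform_to_dict,
)
from .sensitivity import (
    DEFAULT_SWEEP_MM,
    RelocationSpec,
    correlation_scatter,
    correlation_sweep,
    delta_boxplot,
    delta_wss,
    project_specimen,
    relocate_and_reproject,
    wilcoxon_signed_rank,
)

log = logging.getLogger("plaquemap")

REQUIRED_SPECIMEN_FILES = (
    "specimen.json",
    "enface_contours.csv",
    "histology_contours.csv",
    "invivo_contours.csv",
    "exvivo_contours.csv",
    "wss_surface.vtp",
    "landmark_pairs.csv",
)

ALL_STAGES = ("register", "project", "qc", "sensitivity")


@dataclass
class PipelineConfig:
    specimens: dict[str, Path]
    output_dir: Path
    flags: Path | None = None
    projection: ProjectionParams = field(default_factory=ProjectionParams)
    registration: BSplineRegistrationParams = field(default_factory=BSplineRegistrationParams)
    relocation_sweep_mm: tuple[float, ...] = tuple(d for d in DEFAULT_SWEEP_MM if d != 0)
    seed: int = 0
    make_figures: bool = True
    smoothing_window: int = 3

    def validate(self) -> None:
        if not self.specimens:
            raise ValueError("config lists no specimens")
        for sid, d in self.specimens.items():
            d = Path(d)
            if not d.is_dir():
                raise FileNotFoundError(f"specimen {sid}: directory {d} not found")
            for name in REQUIRED_SPECIMEN_FILES:
                if not (d / name).exists():
                    raise FileNotFoundError(f"specimen {sid}: missing input {d / name}")
        if self.flags is not None and not Path(self.flags).exists():
            raise FileNotFoundError(f"flags file {self.flags} not found")

    def to_dict(self) -> dict:
        return {
            "specimens": {k: str(v) for k, v in self.specimens.items()},
            "output_dir": str(self.output_dir),
            "flags": None if self.flags is None else str(self.flags),
            "projection": asdict(self.projection),
            "registration": asdict(self.registration),
            "relocation_sweep_mm": list(self.relocation_sweep_mm),
            "seed": self.seed,
            "make_figures": self.make_figures,
            "smoothing_window": self.smoothing_window,
        }


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cfg = PipelineConfig(
        specimens={str(k): Path(v) for k, v in raw["specimens"].items()},
        output_dir=Path(raw["output_dir"]),
        flags=Path(raw["flags"]) if raw.get("flags") else None,
        projection=ProjectionParams(**raw.get("projection", {})),
        registration=BSplineRegistrationParams(**raw.get("registration", {})),
        relocation_sweep_mm=tuple(raw.get("relocation_sweep_mm", [-0.6, -0.3, 0.3, 0.6])),
        seed=int(raw.get("seed", 0)),
        make_figures=bool(raw.get("make_figures", True)),
        smoothing_window=int(raw.get("smoothing_window", 3)),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

#: skip the non-rigid refinement when contours already agree to within the
#: distance-map rasterization accuracy (avoids warping an exact alignment)
BSPLINE_SKIP_RMS_MM = 0.05


def _landmark_points(pairs: pd.DataFrame, step: str, slice_index: int | None = None):
    grp = pairs[pairs["step"] == step]
    if slice_index is not None:
        grp = grp[grp["slice_index"] == slice_index]
    if len(grp) == 0:
        raise ValueError(f"no landmark pairs for registration step {step!r}")
    grp = grp.sort_values("label")
    return (
        grp[["fixed_x_mm", "fixed_y_mm"]].to_numpy(),
        grp[["moving_x_mm", "moving_y_mm"]].to_numpy(),
    )


def stage_register(specimen_id: str, inputs: dict, cfg: PipelineConfig, outdir: Path) -> dict:
    """Fit the full transform set for one specimen and save it as JSON."""
    pairs = inputs["landmark_pairs"]
    params = cfg.registration

    _, photo_transforms = stack_enface_photos(inputs["enface_photos"])

    fixed_A, moving_A = _landmark_points(pairs, "A")
    sim_A = fit_similarity_from_landmarks(fixed_A, moving_A)
    moving_rigid_A = inputs["invivo_contours"].map_points(sim_A.apply)
    bsp_A = _fit_or_skip(inputs["exvivo_contours"], moving_rigid_A, params)

    fixed_B, moving_B = _landmark_points(pairs, "B")
    sim_B = fit_similarity_from_landmarks(fixed_B, moving_B)
    moving_rigid_B = inputs["exvivo_contours"].map_points(sim_B.apply)
    bsp_B = _fit_or_skip(inputs["enface_contours"], moving_rigid_B, params)

    sims_C = {}
    for sl in inputs["histology_contours"].slice_indices("lumen"):
        fixed_C, moving_C = _landmark_points(pairs, "C", sl)
        sims_C[sl] = fit_similarity_from_landmarks(fixed_C, moving_C)

    chain_invivo = TransformChain(
        [
            (sim_A, "invivo", "invivo_rigid"),
            (bsp_A, "invivo_rigid", "exvivo"),
            (sim_B, "exvivo", "exvivo_rigid"),
            (bsp_B, "exvivo_rigid", "enface"),
        ]
    )
    transforms = {
        "invivo": chain_invivo,
        "exvivo": TransformChain(
            [(sim_B, "exvivo", "exvivo_rigid"), (bsp_B, "exvivo_rigid", "enface")]
        ),
        "histology_per_slice": sims_C,
        "enface_photos": photo_transforms,
    }
    payload = {
        "invivo": transform_to_dict(transforms["invivo"]),
        "exvivo": transform_to_dict(transforms["exvivo"]),
        "histology_per_slice": {
            str(sl): transform_to_dict(t) for sl, t in sims_C.items()
        },
        "enface_photos": [transform_to_dict(t) for t in photo_transforms],
    }
    (outdir / f"transforms_{specimen_id}.json").write_text(json.dumps(payload, indent=1))
    log.info("registered specimen %s (A, B, %d C slices)", specimen_id, len(sims_C))
    return transforms


def _fit_or_skip(fixed: ContourStack, moving: ContourStack, params: BSplineRegistrationParams):
    from .registration.transforms import BSplineTransform2D

    probe = register_contours_bspline(
        fixed,
        moving,
        BSplineRegistrationParams(**{**asdict(params), "iterations": 0}),
    )
    if np.sqrt(probe.initial_metric_) < BSPLINE_SKIP_RMS_MM:
        zero = BSplineTransform2D(
            probe.grid_origin_mm, probe.grid_spacing_mm, np.zeros_like(probe.coefficients)
        )
        zero.metric_trace_ = probe.metric_trace_
        zero.initial_metric_ = probe.initial_metric_
        zero.final_metric_ = probe.initial_metric_
        zero.converged_ = True
        return zero
    return register_contours_bspline(fixed, moving, params)


def load_transforms(outdir: Path, specimen_id: str) -> dict:
    payload = json.loads((outdir / f"transforms_{specimen_id}.json").read_text())
    return {
        "invivo": transform_from_dict(payload["invivo"]),
        "exvivo": transform_from_dict(payload["exvivo"]),
        "histology_per_slice": {
            int(sl): transform_from_dict(t)
            for sl, t in payload["histology_per_slice"].items()
        },
        "enface_photos": [transform_from_dict(t) for t in payload["enface_photos"]],
    }


def transformed_geometry(inputs: dict, transforms: dict) -> dict:
    """Map the WSS surface and all modality contours into the en-face domain."""
    chain_invivo = transforms["invivo"]
    sims_C = transforms["histology_per_slice"]
    histology = ContourStack(
        [
            type(c)(c.slice_index, c.z_mm, c.structure, sims_C[c.slice_index].apply(c.points))
            for c in inputs["histology_contours"]
        ]
    )
    return {
        "wss_surface": chain_invivo.apply_to_surface(inputs["wss_surface"]),
        "invivo_contours": chain_invivo.apply_to_contours(inputs["invivo_contours"]),
        "exvivo_contours": transforms["exvivo"].apply_to_contours(inputs["exvivo_contours"]),
        "histology_contours": histology,
    }


def stage_project(
    specimen_id: str, inputs: dict, transforms: dict, cfg: PipelineConfig, outdir: Path
) -> pd.DataFrame:
    geo = transformed_geometry(inputs, transforms)
    lumen_stack = geo["invivo_contours"].select("lumen")
    centerline = compute_centerline(lumen_stack, cfg.smoothing_window)
    centerline.write_csv(outdir / f"centerline_{specimen_id}.csv")
    table = project_specimen(
        geo["wss_surface"],
        lumen_stack,
        centerline,
        cfg.projection,
        specimen_id=specimen_id,
        thickness_contours=geo["histology_contours"],
    )
    if cfg.make_figures:
        from .binning import section_overlay

        for c in lumen_stack:
            section_overlay(
                geo["wss_surface"],
                c.points,
                c.z_mm,
                centerline.centerpoint(c.slice_index),
                outdir / f"overlay_{specimen_id}_{c.slice_index:03d}.png",
                cfg.projection,
            )
    return table


def stage_qc(
    specimen_id: str, inputs: dict, transforms: dict, cfg: PipelineConfig
) -> pd.DataFrame:
    """Per-section DSC/HD of lumen outlines against the en-face reference.

    type 2 compares en-face vs transformed histology; type 3 compares
    en-face vs transformed in vivo MRI.
    """
    geo = transformed_geometry(inputs, transforms)
    enface = inputs["enface_contours"]
    rows = []
    for sl in enface.slice_indices("lumen"):
        ref = enface.get(sl, "lumen").points
        hist = geo["histology_contours"].get(sl, "lumen").points
        mri = geo["invivo_contours"].get(sl, "lumen").points
        rows.append(
            {
                "specimen_id": specimen_id,
                "slice_index": sl,
                "dsc_type2": dice_between_contours(ref, hist),
                "dsc_type3": dice_between_contours(ref, mri),
                "hd_type2_mm": hausdorff_distance(ref, hist, resample_mm=0.05),
                "hd_type3_mm": hausdorff_distance(ref, mri, resample_mm=0.05),
            }
        )
    return pd.DataFrame(rows)


def stage_sensitivity(
    specimen_id: str,
    inputs: dict,
    transforms: dict,
    baseline: pd.DataFrame,
    cfg: PipelineConfig,
    outdir: Path,
) -> dict:
    geo = transformed_geometry(inputs, transforms)
    lumen_stack = geo["invivo_contours"].select("lumen")
    centerline = compute_centerline(lumen_stack, cfg.smoothing_window)
    tables = {0.0: baseline}
    for dz in cfg.relocation_sweep_mm:
        tables[float(dz)] = relocate_and_reproject(
            geo["wss_surface"],
            lumen_stack,
            centerline,
            cfg.projection,
            RelocationSpec(dz),
            specimen_id=specimen_id,
            thickness_contours=geo["histology_contours"],
        )

    delta_rows = []
    per_location = {}
    wilcoxon_rows = []
    for dz, table in tables.items():
        if dz == 0.0:
            continue
        deltas = delta_wss(baseline, table)
        per_location[dz] = deltas["per_location"]
        grand = deltas["grand"].iloc[0]
        delta_rows.append({"dz_mm": dz, **grand.to_dict()})
        deltas["per_bin"].assign(dz_mm=dz).to_csv(
            outdir / f"sensitivity_bins_{specimen_id}_dz{dz:+.1f}.csv", index=False
        )
        for stat in ("mean", "min", "max"):
            col = f"{stat}_wss_pa"
            keep = baseline["included"].astype(bool).to_numpy() & baseline[col].notna().to_numpy()
            p = wilcoxon_signed_rank(
                baseline.loc[keep, col].to_numpy(), table.loc[keep, col].to_numpy()
            )
            wilcoxon_rows.append({"dz_mm": dz, "statistic": stat, "p_value": p})

    corr = {
        stat: correlation_sweep(tables, stat)
        for stat in ("mean", "min", "max")
    }
    return {
        "tables": tables,
        "grand_deltas": pd.DataFrame(delta_rows),
        "per_location_deltas": per_location,
        "wilcoxon": pd.DataFrame(wilcoxon_rows),
        "correlations": corr,
    }


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, stages=None) -> Path:
    """Run the requested stages for every specimen; returns the run directory.

    Outputs: per-specimen transforms JSON and centerline CSV, the
    combined bin table, QC summary and tally CSVs, sensitivity reports,
    QC overlay figures and ``manifest.json``.
    """
    stages = tuple(stages or ALL_STAGES)
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, stages, outdir)
    except Exception as exc:
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, stages, outdir: Path) -> Path:
    all_inputs = {}
    for sid, directory in config.specimens.items():
        try:
            all_inputs[sid] = read_bundle(directory)
        except Exception as exc:
            raise RuntimeError(f"stage=load specimen={sid}: {exc}") from exc

    all_transforms = {}
    for sid, inputs in all_inputs.items():
        try:
            if "register" in stages:
                all_transforms[sid] = stage_register(sid, inputs, config, outdir)
            else:
                all_transforms[sid] = load_transforms(outdir, sid)
        except Exception as exc:
            raise RuntimeError(f"stage=register specimen={sid}: {exc}") from exc

    needs_table = bool({"project", "qc", "sensitivity"} & set(stages))
    combined = None
    if "project" in stages:
        tables = []
        for sid, inputs in all_inputs.items():
            try:
                tables.append(stage_project(sid, inputs, all_transforms[sid], config, outdir))
            except Exception as exc:
                raise RuntimeError(f"stage=project specimen={sid}: {exc}") from exc
        combined = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        write_bin_table(combined, outdir / "bin_table.csv")
    elif needs_table:
        combined = read_bin_table(outdir / "bin_table.csv")

    if combined is not None and config.flags is not None:
        combined = apply_exclusions(combined, read_flags(config.flags))
        write_bin_table(combined, outdir / "bin_table.csv")

    if "qc" in stages:
        metrics = []
        for sid, inputs in all_inputs.items():
            try:
                metrics.append(stage_qc(sid, inputs, all_transforms[sid], config))
            except Exception as exc:
                raise RuntimeError(f"stage=qc specimen={sid}: {exc}") from exc
        metrics = pd.concat(metrics, ignore_index=True)
        metrics.to_csv(outdir / "qc_metrics.csv", index=False, float_format="%.6g")
        qc_summary(metrics, combined).to_csv(
            outdir / "qc_summary.csv", index=False, float_format="%.6g"
        )
        exclusion_tally(combined).to_csv(outdir / "qc_tally.csv", index=False)

    if "sensitivity" in stages:
        grand_all = []
        for sid, inputs in all_inputs.items():
            try:
                baseline = combined[combined["specimen_id"] == sid].reset_index(drop=True)
                result = stage_sensitivity(
                    sid, inputs, all_transforms[sid], baseline, config, outdir
                )
            except Exception as exc:
                raise RuntimeError(f"stage=sensitivity specimen={sid}: {exc}") from exc
            result["grand_deltas"].assign(specimen_id=sid).to_csv(
                outdir / f"sensitivity_grand_{sid}.csv", index=False
            )
            result["wilcoxon"].assign(specimen_id=sid).to_csv(
                outdir / f"sensitivity_wilcoxon_{sid}.csv", index=False
            )
            for stat, corr in result["correlations"].items():
                corr.to_csv(
                    outdir / f"sensitivity_correlation_{sid}_{stat}.csv", index=False
                )
            grand_all.append(result["grand_deltas"].assign(specimen_id=sid))
            if config.make_figures and result["per_location_deltas"]:
                delta_boxplot(
                    result["per_location_deltas"], outdir / f"fig_deltas_{sid}.png"
                )
                sl = sorted(all_inputs[sid]["enface_contours"].slice_indices("lumen"))[
                    len(all_inputs[sid]["enface_contours"].slice_indices("lumen")) // 2
                ]
                correlation_scatter(
                    result["tables"], sid, sl, outdir / f"fig_correlation_{sid}.png"
                )
        if grand_all:
            pd.concat(grand_all, ignore_index=True).groupby("dz_mm").mean(
                numeric_only=True
            ).reset_index().to_csv(outdir / "sensitivity_grand_combined.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": list(stages),
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    import shapely

    return {
        "plaquemap": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "shapely": shapely.__version__,
    }
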