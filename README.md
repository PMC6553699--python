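# plaquemap

Register patient-specific wall shear stress (WSS) maps to serial histology
of a sectioned vessel specimen, using the stack of en-face photos of the
cut faces as the shared coordinate frame.

The package implements the full desk-scale pipeline on synthetic
specimens with known ground truth:

* **phantom** — generates single-lumen tube specimens: en-face photo
  stack with pin landmarks, histology / in vivo MRI / ex vivo MRI
  contour stacks deformed by known similarity + B-spline perturbations,
  a lumen-surface WSS field `baseline + gradient·z + amplitude·cos θ`,
  and analytic per-bin truth values.
* **imaging_io** — data types and formats: volumes (NIfTI, MetaImage),
  photos (PNG/TIFF + JSON sidecar), contours/landmarks/bin tables (CSV),
  surfaces with a `wss_pa` vertex scalar (VTK PolyData `.vtp`, PLY),
  transforms (JSON).
* **registration** — landmark-based rigid en-face stack assembly,
  closed-form least-squares similarity fitting, contour-driven 2D
  B-spline free-form deformation (signed-distance-map mean-squares
  metric, adaptive-step stochastic gradient descent), transform chaining
  and volume resampling.
* **centerline** — per-slice maximal-inscribed-circle centers via the
  contour's Voronoi diagram, smoothed along z.
* **binning** — projection of the surface WSS field onto each section
  (±0.3 mm axial window, vertex pooling), 8 half-open radial wedges
  about the centerline point, per-bin WSS mean/min/max, plaque thickness
  (mean shortest lumen→media distance) and component areas.
* **qc** — Dice coefficient and symmetric curve Hausdorff distance,
  error-flag exclusion bookkeeping (three error types, set-union
  semantics) and before/after-exclusion summaries.
* **sensitivity** — axial relocation of the WSS field
  (default ±0.3 / ±0.6 mm sweep), per-bin |ΔWSS| statistics, exact
  small-sample Wilcoxon signed-rank, Pearson correlation of WSS vs
  plaque thickness per axial location, and the robustness of that
  correlation under mismatch.

## Command line

Generate a synthetic specimen directory:

```sh
cat > spec.yaml <<EOF
n_sections: 12
wss_axial_gradient_pa_per_mm: 0.5
wss_circumferential_amplitude_pa: 1.0
deformation_magnitude_mm: 1.0
rng_seed: 7
EOF
plaquemap phantom spec.yaml -o specimens/CEA1
```

Run the pipeline (all stages, or `register` / `project` / `qc` /
`sensitivity` individually against the same output directory):

```sh
cat > config.yaml <<EOF
specimens:
  CEA1: specimens/CEA1
output_dir: runs/demo
relocation_sweep_mm: [-0.6, -0.3, 0.3, 0.6]
seed: 0
EOF
plaquemap all config.yaml
```

Outputs land in `output_dir`: fitted transforms (JSON), centerline and
combined radial bin table (CSV), QC metric/summary/tally tables (CSV),
per-relocation sensitivity reports (CSV), per-section overlay and
sensitivity figures (PNG), plus `manifest.json` recording the config
hash and package versions. Manual error flags can be supplied via
`flags: flags.csv` (columns `specimen_id, slice_index, bin_index,
error_type`).

## Conventions

All world coordinates are mm; z is the axial direction (caudal →
cranial), sections are 1 mm apart by default and an en-face photo
represents its section's proximal face. Contours are closed, simple,
stored counter-clockwise. Radial wedges are measured counter-clockwise
from the +x axis with half-open boundaries; a positive relocation moves
the WSS field cranially.
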