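# petgeom

Hotspot-geometry PET biomarkers. From a 3D SUV volume, `petgeom` computes the
normalized distance from the uptake hotspot (the SUVmax voxel) to the tumor
centroid (**NHOCmax**) and the minimum normalized distance from the hotspot to
the tumor perimeter (**NHOPmax**), alongside the conventional metabolic
parameters SUVmax, SUVmean, MTV, and TLG. Both distances are normalized by the
radius of a sphere with the same volume as the segmented lesion, so NHOCmax
grows and NHOPmax shrinks as the hotspot migrates toward the lesion edge.

The package also ships:

- a **phantom generator** (spheres/ellipsoids with a planted hotspot at a
  controlled normalized offset, Gaussian PSF blur, noise) with analytic
  ground-truth NHOC/NHOP, and a **cohort simulator** whose recurrence and
  disease-free-survival outcomes carry a protective NHOPmax effect;
- the downstream **recurrence-prediction statistics**: Spearman correlation
  matrices, ROC analysis with stratified-bootstrap AUC CIs and Youden cut-off
  selection, univariate/multivariate logistic and Cox (Efron ties) regression,
  Kaplan-Meier curves with the log-rank test, and table-shaped CSV reports.

## Pipeline

1. Resample the SUV volume to an isotropic grid (default 3 mm, trilinear).
2. Locate the hotspot (maximum SUV; lexicographic tie-break).
3. Segment the lesion: 26-connected component of `SUV >= 0.40 * SUVmax`
   containing the hotspot; the perimeter is the outermost voxel layer (mask
   voxels with a 6-neighbor outside the mask).
4. Compute MTV (mL), SUVmean, TLG = SUVmean x MTV, the geometric centroid,
   the equivalent-sphere radius `(3V / 4 pi)^(1/3)`, NHOCmax, and NHOPmax.
   All distances are between voxel centers, in mm.

## CLI

```bash
petgeom phantom --out lesion.nii --offset 0.4 --seed 7        # synthetic tumor + truth JSON
petgeom extract --in lesion.nii --out metrics.csv             # one-row metrics CSV
petgeom cohort  --n 400 --out cohort.csv --seed 7             # simulated cohort CSV
petgeom analyze --in cohort.csv --outdir reports/             # ROC/logistic/Cox/KM reports
petgeom all     --outdir demo/ --seed 7                       # end-to-end demo
```

All commands are deterministic given `--seed`; the effective configuration is
echoed to a JSON sidecar. Images are NIfTI (mm spacing from the header, loaded
in canonical RAS order); tables are CSV.

## Acceptance battery

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes every acceptance criterion from scratch (phantom recovery, closed
forms, brute-force oracle equivalences, regression/survival simulation
recoveries) and prints a PASS/FAIL line per criterion. There are no numeric
acceptance targets to report — the clinical point estimates would require an
undeposited patient dataset — so the JSON output is an empty object.

## Layout

- `src/petgeom/image_core.py` — `PETVolume`, isotropic resampling, hotspot search
- `src/petgeom/segmentation.py` — relative-threshold segmentation, perimeter
- `src/petgeom/metrics.py` — MTV/SUV/TLG/centroid/NHOC/NHOP and `extract_metrics`
- `src/petgeom/phantom.py` — phantom generator, cohort simulator
- `src/petgeom/cohort_stats.py` — Spearman, ROC/Youden, logistic, Cox, KM/log-rank, reports
- `src/petgeom/io_cli.py` — NIfTI I/O, run config, `petgeom` CLI
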