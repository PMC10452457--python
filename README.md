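# asset-lv

Automatic generation of the AHA 17-segment model of the left-ventricular
myocardium (LVM) from a binary LV mask and a single RV-insertion point.

Given an LV segmentation (NIfTI) and the physical-mm coordinates of the
right-ventricular insertion point, the pipeline:

1. estimates the parasternal long axis (PLAX) as the first principal
   component of the LV mask voxel coordinates, oriented base → apex;
2. builds the myocardial shell as a standardized 8 mm inner ring on the LV
   (anisotropy-aware Euclidean distance transform), with an optional basal
   plane cut;
3. places three short-axis planes that split the shell into basal, mid and
   apical regions of equal axial length, plus the apex cap distal to the
   cavity tip;
4. divides basal and mid regions into six 60° sectors and the apical region
   into four 90° sectors (boundaries at −15°/75°/165°/255°), with azimuth 0
   at the RV-insertion direction, producing labels 1–17;
5. post-processes each segment by morphological closing with a Euclidean
   ball, preserving the exact partition of the shell.

Also included: axis-comparison primitives (mean line distance, line angle),
per-segment Dice / mean-distance-to-agreement evaluation, and a synthetic
prolate-spheroid LV phantom with a closed-form analytic label oracle used as
the test bed.

## CLI

```bash
# generate the synthetic phantom (mask, truth labels, RV point, true axis)
asset phantom -o phantom/

# run the full 17-segment pipeline
asset segment --lv phantom/lv.nii.gz --rv-point phantom/rv.json \
    [--physician-axis axis.json] [--mode voxel|surface_closing] \
    [--apex-rule cavity_tip|fraction:F] [--closing-radius MM] \
    [--thickness MM] [--flip-rotation] -o out/

# per-segment DSC/MDA table between two label maps
asset evaluate --a out/segments.nii.gz --b phantom/truth.nii.gz -o report.csv

# mean distance (mm) and angle (deg) between two axis files
asset compare-axes --a axis1.json --b axis2.json
```

`asset segment` writes the label map (`segments.nii.gz`, integers 0–17 with
the input affine), a label → name → angular-interval table (`segments.csv`),
the fitted axis (`plax.json`) and a full provenance snapshot
(`provenance.json`: config, axis, planes, scheme, warnings, stage timings).

Point and axis files are JSON with physical-mm coordinates in the image's
affine frame, e.g. `{"point": [x, y, z]}` or
`{"points": [[basal...], [apical...]]}`.

## Conventions

- All geometry is computed in physical mm via the stored affine; voxel
  indices appear only at I/O boundaries; no silent axis flipping.
- Azimuth 0 points at the RV insertion; positive rotation follows the
  right-hand rule about the base→apex direction so increasing azimuth runs
  anterior → anterolateral → … → anteroseptal.  `--flip-rotation` inverts
  the chirality.
- Angular and axial intervals are closed-left/open-right (final interval
  closed); voxels are classified by their center coordinate.
- MDA is boundary-voxel-center to boundary-voxel-center (6-connectivity
  boundaries, symmetric mean), so reported values are bit-reproducible.
- Segment averages are unweighted across labels (mean ± SD).

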