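# stentmorph

Morphometric measurement of thoracic aortic stent-grafts across follow-up
CT timepoints, built on per-ring peak observation points.

From a CT-like HU volume (or a binary stent mask from any source) the
pipeline:

1. **segments** the stent with an inclusive HU threshold band
   (default 1200–2200) and connectivity-based region selection;
2. **separates support rings** as 26-connected components, orders them
   proximal→distal, and fits an interpolating cubic-spline centerline
   through the ring centroids;
3. **extracts peak observation points** per ring: angular-sector axial
   extrema along the centerline frame, amplitude-fraction elimination of
   strut points, and 2 mm sphere-merge clustering;
4. **registers** each timepoint's point set to a skeletal origin landmark
   (pure translation);
5. **measures** three parameter families between periods:
   - end-slip vector (componentwise end-ring midpoint displacement,
     earlier − later),
   - characteristic ring diameter ρ (max pairwise peak distance) and ring
     rate R_k = (ρ_k/ρ_1)²,
   - ring deflection angle β (mean signed projected rotation of the
     peaks about the local centerline axis),
   plus method-agreement statistics (difference mean/SD, squared Pearson
   correlation) and missing-rate / distance scoring against reference
   point sets.

Because no patient data ships with the package, a **phantom module**
generates parametric multi-ring zig-zag stents (triangle-wave apices,
straight or arc centerlines), voxelizes them into masks and CT-like HU
volumes, and applies ground-truth-tracked deformations (translation,
radial scaling, twist, bend) so every stage is validated against analytic
apex coordinates.

## CLI

All subcommands accept `--config config.yaml` (keys mirror `RunConfig`)
and `--log-level`. Exit codes: 0 success, 2 validation error, 3 stage
failure.

```bash
# seeded 2-timepoint phantom with an imposed deformation
stentmorph phantom --rings 7 --apices 5 --seed 42 \
    --deform translate=3,0,0@T2 --out case/

# full pipeline from the generated manifest
stentmorph run --manifest case/manifest.yaml --out case/out/

# individual stages
stentmorph segment --in ct.nii.gz --lo 1200 --hi 2200 --out mask.nii.gz
stentmorph rings   --mask mask.nii.gz --min-volume 50 --out rings.json
stentmorph peaks   --mask mask.nii.gz --orientation proximal --out peaks.csv
stentmorph compare --a auto.csv --b manual.csv --threshold 5
stentmorph measure --manifest points_manifest.yaml --out report.json
```

Volumes are NIfTI-1 (spacing/origin in the affine, world mm); point sets
are CSV (`case_id, timepoint, ring_index, peak_index, orientation, x_mm,
y_mm, z_mm, source`) with a JSON metadata sidecar; reports are JSON with
sorted keys and no timestamps, so reruns with the same seed/config are
byte-identical.

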