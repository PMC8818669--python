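# fiapipe

Analysis pipeline for fusiform vessel dilations: morphological profiling of
vessel lumens along their centerline, automated restoration of the
pre-pathological ("healthy") wall, fast virtual deployment of braided
flow-diverter stents, boundary-condition helpers and hemodynamic index
computation (AWSS, OSI, RRT, OVI, KE) for fusiform / healthy / treated
three-state comparisons.

No patient data are bundled; a first-class synthetic-data module generates
every input with known ground truth — parametric curved tubes with Gaussian
circumferential dilations, a two-harmonic cardiac waveform stand-in and
analytic pulsatile (Womersley) velocity/wall-shear fields.

## Modules

| Module | Purpose |
| --- | --- |
| `fiapipe.geometry` | Surface meshes, centerlines, rotation-minimizing frames, arc-length resampling |
| `fiapipe.formats` | STL (ASCII/binary), OBJ, centerline CSV / OBJ-polyline I/O |
| `fiapipe.morphology` | Ray-cast cross-sectional-area profiles, nominal diameter, 1.5x-ratio fusiform detection, morphology report (CSA_A, CSA_PV, RI) |
| `fiapipe.healthy` | Target healthy-radius interpolation and constrained local smoothing that removes the dilation |
| `fiapipe.stenting` | Braided-stent template, wire-length-conserving deployment (diameter-pitch coupling), apposition and metal-coverage maps |
| `fiapipe.flow_bc` | Inflow waveform scaling, Murray / shape-based outlet flow splitting |
| `fiapipe.indices` | AWSS, OSI, RRT, OVI, KE and weighted summaries over one cardiac cycle |
| `fiapipe.fieldio` | CSV-per-timestep (+ manifest) and HDF5 field-series containers |
| `fiapipe.synthetic` | Vessel/waveform/field generators with ground truth |
| `fiapipe.pipeline`, `fiapipe.cli` | Per-case orchestration, three-state comparison, CLI |

All coordinates are millimeters (areas mm²); shear is Pa, velocity m/s.
Centerline frames use parallel transport rather than Frenet frames so they
remain defined on straight segments (the frame convention for "perpendicular"
section planes is a documented implementation choice).

## CLI

```sh
# generate a synthetic fusiform vessel
fiapipe synth --length 30 --base-radius 2 --peak-radius 3.2 \
    --dilation-center 15 --sigma 0.75 --edge-length 0.3 \
    --mesh-out vessel.obj --centerline-out centerline.csv

# cross-sectional-area profile and dilation detection
fiapipe profile --mesh vessel.obj --centerline centerline.csv \
    --spacing 0.5 --n-rays 180 --out profile.csv
fiapipe detect --profile profile.csv --window 5 --out detection.json

# healthy restoration and virtual stenting
fiapipe restore --mesh vessel.obj --centerline centerline.csv \
    --region detection.json --out healthy.obj
fiapipe stent --mesh vessel.obj --centerline centerline.csv \
    --length 10 --diameter 4 --s-distal 27 --out stent.json

# full case from a YAML/JSON config
fiapipe run --config case.yaml --out report.json
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. Logs go to
stderr; results only to files.

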