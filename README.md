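# manipkin

Quantitative kinetics and kinematics of prone cervical HVLA ("high-velocity,
low-amplitude") manipulation trials, recorded with marker-based motion
capture (200 Hz) synchronized to two force plates (1000 Hz).

The pipeline covers:

- **trial I/O** — C3D and a documented CSV dialect, marker-label aliasing,
  zero-phase Butterworth filtering, occlusion gap filling, clock alignment;
- **force-phase analysis** — baseline estimation, segmentation of the
  vertical ground-reaction-force curve into stretching / triggering / return
  phases via the A/B/C/D turning points (E/F/G/H for the mirrored
  right-rotation event), loaded-force peaks (peak minus baseline), and
  detection of the mid-trial subject position-change artifact (coincident
  plate-1 trough / plate-2 peak), which is excluded from phase metrics;
- **rigid-body kinematics** — head and thorax marker clusters, per-frame
  least-squares pose (SVD/Kabsch with reflection guard), axial head-on-thorax
  rotation by quaternion swing–twist about the thorax vertical axis (Cardan
  X-Y-Z selectable), mid-shoulder / head-vertex virtual points;
- **event metrics** — operator trigger time from the active acromion's
  vertical displacement (onset point I to peak displacement II), neck
  extension amplitude (max head-vertex-to-mid-shoulder distance minus its
  resting value, in mm), per-side metric records with provenance;
- **synthetic data** — a trial generator with exact ground truth (baseline,
  stretch ramp, raised-cosine thrust, artifact, rotation and extension
  ramps, operator thrust excursion, configurable noise) and cohort sampling
  from truncated-normal parameter distributions;
- **statistics** — Shapiro–Wilk, mean-centred Levene, paired t (Welch
  fallback for independent comparisons), cohort summary tables (CSV +
  Markdown).

## CLI

```sh
# generate a 10-subject synthetic cohort (CSV trials + ground-truth JSON)
manipkin simulate --n-subjects 10 --seed 42 --out cohort/

# run the full pipeline over every trial directory
manipkin analyze --trials cohort/ --config examples/analysis.yaml --out report/

# cohort summary tables from the per-trial metrics
manipkin report --metrics report/metrics.csv --out report/summary/
```

`analyze` writes `metrics.csv` (one row per trial side), `phases.csv`
(A/B/C/D, baseline, loaded forces), per-trial angle series, and
`run_info.json` with the config hash. `--strict` exits nonzero on any
partial record. See `examples/analysis.yaml` and `examples/cohort.yaml` for
the full configuration surface.

## Data formats

**CSV dialect** — a trial is a pair of files, each starting with a
`# rate_hz=<rate>` comment:

- `markers.csv`: header `time,<label>_X,<label>_Y,<label>_Z,...`; positions
  in metres; occluded frames are empty/NaN.
- `forces.csv`: header
  `time,plate1_Fx,plate1_Fy,plate1_Fz,plate2_Fx,plate2_Fy,plate2_Fz`;
  forces in newtons.

**C3D** — float-storage files with POINT (mm) and ANALOG groups; analog
channels named `plate<k>_F<x|y|z>` map to the two force plates.

Axis convention: X frontal (left−/right+), Y sagittal (back−/front+),
Z vertical (up+); vertical plate force is reported so pressing harder
increases the value. All event times are seconds from trial start.

## Layout

```
src/manipkin/
  trial_io.py        data model, CSV/C3D I/O, filtering, clocks, gaps
  _c3d.py            minimal C3D codec (float storage)
  rigid_kinematics.py  Kabsch poses, swing–twist axial angle, virtual points
  force_phases.py    GRF phase segmentation, loaded forces, artifact
  event_metrics.py   trigger time, extension amplitude, per-trial assembly
  synthetic_data.py  ground-truth trial/cohort generator
  stats_report.py    statistical tests and cohort tables
  cli.py, config.py, errors.py
tests/               unit, property (hypothesis), oracle and acceptance suites
scripts/acceptance.py
```
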