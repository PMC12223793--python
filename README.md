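# aoctel — airway OCT elastography

Analysis pipeline for rotational-catheter (anatomical OCT) airway scans:
from polar intensity frame stacks plus an intraluminal pressure trace to
normalized cross-sectional compliance (nCsC) per scan, and onward to
study-level statistics. A synthetic airway/ventilator/scanner simulator
provides ground truth so every stage is testable without real acquisitions.

## What it does

- **`aoctel.synth`** — generates ground truth: a thick-walled linearly
  elastic tube (plane-strain Lamé solution for the analytic nCsC) driven by
  a pressure-controlled ventilator waveform (default 20 breaths/min, MIP
  18 cmH2O, 5 kHz pressure channel with ~1.32 cmH2O sensor noise), rendered
  into polar frames (default 1152 depth px over 12.5 mm × 1248 angular
  columns at 40 Hz) with catheter-sheath rings, multiplicative speckle,
  log-linear sensitivity roll-off (105 dB at 1 mm → 55 dB at 8.5 mm),
  optional catheter eccentricity and cardiac modulation, and fold-over
  aliasing for radii beyond the imaging range.
- **`aoctel.segment`** — recovers the air–tissue interface per angular
  column (first-rise detector with circular median smoothing and optional
  seed depths), calibrates the pixel scale from the 0.85 mm-OD sheath,
  documents bottom-contact columns, mirror-corrects fold-over sectors
  (`r_corrected = 2·depth − r_apparent`), and integrates the boundary into a
  per-frame cross-sectional area (CSA).
- **`aoctel.elasto`** — pairs the pressure channel with frame windows,
  detects respiratory cycles, extracts per-cycle CSA/pressure extrema, and
  computes CC = ∂CSA/∂p and nCsC = 100·CC/CSĀ (%/cmH2O) with ±5-frame
  uncertainty windows around each extremum.
- **`aoctel.stats`** — numeric covariate coding (intensity 1–3, time in
  hours with −1 = pre-treatment, position 0 = carina to 1 = larynx),
  multiway ANOVA with interaction products, and OLS regression (ordinal
  logit available for injury grades).
- **`aoctel.pipeline`** — end-to-end orchestration with YAML configs,
  reproducibility manifests and summary plots.

## CLI

```sh
# generate a synthetic scan (stack.tiff + geometry.json + pressure.csv + ground truth)
aoctel synth --config synth_cfg.yaml --seed 7 --out scan_dir

# segment a stack into boundary.csv + csa.csv
aoctel segment --stack scan_dir/stack.tiff --geometry scan_dir/geometry.json --out seg_dir

# compliance from CSA + pressure
aoctel elasto --csa seg_dir/csa.csv --pressure scan_dir/pressure.csv --out result.csv

# study statistics from per-scan results + metadata
aoctel stats --results results.csv --metadata meta.csv --out stats_dir

# single-scan or multi-scan study end to end
aoctel run --config run_cfg.yaml --seed 1
```

Exit codes: 0 success, 2 rejected scan (catheter contact, too few cycles,
no pressure modulation), 1 any other error.

Example single-scan `run` config:

```yaml
stack: scan_dir/stack.tiff
geometry: scan_dir/geometry.json
pressure: scan_dir/pressure.csv
out_dir: out
scan_id: scanA
seed: 7
```

## Notes

- Frame timestamps are rotation starts; pressure–frame pairing uses the
  half-open window `[t_f, t_f + 1/frame_rate)`.
- Where the lumen approaches the imaging range, the mirrored fold-back can
  merge with the directly imaged wall; those bottom-contact columns are
  pinned to the bottom row and flagged rather than guessed (the original
  workflow resolved them manually). A detached band between two
  bottom-attached sectors is interpreted as fold-over and mirror-corrected.
- All randomness is behind a single integer seed per stage; identical
  config + seed reproduce byte-identical result CSVs.
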