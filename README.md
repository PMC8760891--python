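# perfquant

Fully automated pixel-wise quantitative myocardial perfusion mapping
from dynamic first-pass contrast-enhanced image series.

Given a dual-sequence perfusion study — a low-resolution arterial-input-
function (AIF) series plus three myocardial short-axis slices per
heartbeat, with two proton-density (PD) frames per slice — the pipeline
runs five stages with no operator interaction:

1. **Motion correction** (`perfquant.preprocess`): per-frame rigid
   in-plane translation, estimated from consecutive-frame cross-
   correlation on high-passed images, outlier-checked, integrated, and
   polished against an iteratively re-averaged reference.
2. **Surface-coil intensity correction** (`perfquant.preprocess`): a
   smooth multiplicative gain field estimated from the PD frames.
3. **Automatic segmentation** (`perfquant.autoseg`): LV blood-pool
   detection on the AIF series (the later-arriving of the two largest
   enhancing components — the right ventricle enhances first),
   myocardial annulus detection, and first-pass timing (foot / peak /
   end) from the AIF curve.
4. **Pixel-wise quantification** (`perfquant.quantify`): baseline
   normalization, resampling to a uniform grid, and Fermi-constrained
   deconvolution of every myocardial pixel against the AIF, yielding
   myocardial blood flow (MBF, ml/g/min) maps; stress/rest map pairs
   give myocardial perfusion reserve (MPR).
5. **Segmental analysis and statistics** (`perfquant.quantify`,
   `perfquant.stats`): 18-segment / 9-coronary-territory tables,
   relative measures (rMBF, rMPR) against the most-normal hyperemic
   territory, per-patient/per-vessel minima, and a diagnostic-accuracy
   layer (ROC with DeLong errors and tests, Youden thresholds, McNemar,
   Mann-Whitney, Pearson, Bland-Altman).

A synthetic-study generator (`perfquant.phantom`) produces studies with
known ground-truth flow, coil shading, frame-wise motion, and noise, so
every stage is testable without any data download.

## CLI

```bash
# generate a synthetic study (archive dialect) with ground truth
perfquant phantom --seed 7 --out study_dir --ischemic

# run the full pipeline; writes NIfTI/CSV maps, curves, traces, tables
perfquant run --study study_dir --out results_dir [--config cfg.yaml] \
              [--condition stress|rest|both] [--dialect archive|dicom]

# diagnostic-accuracy report from per-unit summary minima + truth labels
perfquant stats --segments summaries.csv --truth labels.csv --out acc_dir
```

Config keys for `run` (YAML): `smoothing_scale_px`, `max_shift_px`,
`n_reference_passes`, `baseline_n`, `n_sectors`, `reference_angle`,
`resample_dt_s`, `map_n_starts`, `motion_correction`, `bias_correction`.

## Conventions worth knowing

- **Units.** Image intensities are arbitrary signal units; physical
  meaning enters after baseline subtraction.  Fermi amplitudes are
  stated in ml/g/min with time in seconds; the tissue forward model
  carries the 60 s/min conversion, and reported MBF is the
  impulse-response value at the delay, `F / (1 + exp(-k*w))`.
- **Sectors.** Sector 1 starts at the anterior reference angle (default
  straight up) and proceeds counterclockwise; sector pairs (1,2), (3,4),
  (5,6) map to the LAD, RCA, and CX territories on every slice.
- **Registration scope.** Translation-only; nonrigid and through-plane
  motion are out of scope.
- **Failure policy.** Failed pixel fits are flagged and left NaN (never
  clamped), so they stay auditable in the segment tables.
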