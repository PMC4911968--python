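# planarquant

Planar kidney activity quantification on synthetic SPECT/CT phantoms.

Planar (2D) gamma-camera dosimetry estimates organ activity from anterior
and posterior whole-body images, subtracting a nearby background region of
interest (ROI) to correct for over- and underlying tissue activity.  Where
that background ROI is placed strongly affects the result.  `planarquant`
provides a fully synthetic test bench for this problem:

* **phantom** — labelled voxel phantoms (torso, kidneys, hot cranio-ventral
  liver/spleen/tumour surrogates) with known ground-truth activity
  concentrations, Gaussian PSF blur and Poisson counting noise;
* **attenuation_projection** — CT (HU) to linear-attenuation conversion
  (`mu = mu_w * (1 + HU/1000)`) and attenuated anterior/posterior planar
  forward projection with a half-voxel self-attenuation convention;
* **voi_geometry** — automatic construction of the kidney VOI, body mask
  (count threshold), projection-column VOI, true-background VOI
  (column minus kidney), ten 36° sector background ROIs (B1–B10) at a
  2-pixel gap and 4-pixel width around the kidney silhouette, and the
  surrounding ROI B11; plus measurement of the kidney/patient thicknesses
  `t_k`, `t_p`, dorsal depth `d_k` and volume `v_k`;
* **quantify** — scaled-background net counts and the conjugate-view
  (geometric mean of both views) and posterior-view (single view,
  depth-corrected) activity-concentration estimators, with explicit
  negative-net-count refusal signals;
* **stats_report** — background-to-true-background ratios (BTR), CVs,
  negative-count fractions (CNC/PNC), relative activity concentrations
  against the volumetric reference, paired t-tests, and cohort summary
  tables (`table1.csv`, `fig4.csv`);
* **io_cli** — NIfTI/MetaImage volume I/O, YAML configuration, and a CLI.

Angle convention for the sector ROIs: 0° points cranial (+z) and angles
increase toward the patient's left (+x) in the projection plane; sector
B1 covers [0°, 36°), B2 [36°, 72°), … B10 [324°, 360°).

## CLI

Every pipeline stage is independently runnable; all accept a YAML config
mirroring `planarquant.pipeline.PipelineConfig` (defaults: 128×128×64 grid
at 2.21/2.21/4.42 mm, body threshold 5 counts, gap 2, width 4, 10 sectors,
`mu_w` = 0.136 cm⁻¹):

```sh
planarquant phantom  -c config.yaml -o out/       # build + save a phantom
planarquant project  -c config.yaml -o out/       # planar projections (CSV)
planarquant vois     -c config.yaml -o out/       # masks, sector ROIs, geometry
planarquant quantify -c config.yaml -o out/       # per-subject result rows
planarquant report   --rows out/subject_000.csv --rows out/subject_001.csv -o out/
planarquant run      -c config.yaml -o out/ --seed 1   # full cohort study
```

`run` writes `rows.csv` (one row per subject × kidney × background ROI),
`table1.csv` (mean BTR, CV, CNC%, PNC% per ROI and side), `fig4.csv`
(mean relative AC per ROI × method, restricted to ROIs with ≤10% negative
net counts, with paired ConjV-vs-PostV t-tests) and `params.json`.
A minimal config:

```yaml
cohort: torso        # or "slab" (analytic validation geometry)
n_subjects: 20
seed: 1
psf_fwhm_mm: 8.0
poisson: true
```

All randomness derives from the single master seed; a fixed config is
bit-reproducible.

## Limitations

No scatter or collimator modelling, no OSEM reconstruction, no absorbed
dose calculation.  Per-ROI t-tests are reported without multiple-testing
correction.
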