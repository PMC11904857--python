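# cmquant

Quantification pipeline for iPSC-derived cardiomyocyte phenotyping assays,
with synthetic ground-truth generators for every input modality:

* **Sodium current** (`cmquant.sodium`): peak extraction from voltage-clamp
  step families, current density, I–V curves, reversal-potential
  estimation, chord-conductance transform, and Boltzmann fits of
  steady-state activation (ascending form) and inactivation/availability
  (descending form).
* **Action potentials** (`cmquant.ap`): APA, APD30/50/90 (from the
  max-dV/dt instant, interpolated crossings), upstroke velocity,
  depolarization time, resting potential; beat-wise extraction averaged
  per cell.
* **Calcium transients** (`cmquant.calcium`): stimulus-aligned segmentation
  and averaging of paced ratiometric recordings, then amplitude, Tp10/50,
  Tp, Tb10/50, transient duration (90% recovery), time to baseline,
  release/return velocities, and release/recovery AUCs.
* **Striation morphometry** (`cmquant.morphometry`): bilinear line-profile
  extraction from two-channel images, sub-pixel extremum detection, actin
  shift (Z-disk maxima to nearest actin minima), Z-disk/band FWHM above the
  local trough, and background-corrected intensity ratios.
* **Group statistics** (`cmquant.stats`): two-sided Mann–Whitney U
  (exact enumeration for small tie-free samples, tie/continuity-corrected
  normal approximation otherwise), mean/SD/SEM summaries, star
  annotations, and long-format two-group comparison tables.
* **Synthetic data** (`cmquant.synth`): an m³h gating model driving
  voltage-clamp step and two-pulse availability families, parametric paced
  action potentials with exactly recoverable APD targets, a closed-form
  rise×decay calcium-transient kernel, striated two-channel test images,
  and a cohort builder with per-cell parameter jitter and exact stored
  ground truth. Mutant presets encode rigid gating-midpoint translations
  (+5 mV activation; −11 mV inactivation) plus a conductance reduction.
* **IO / pipeline / CLI** (`cmquant.io`, `cmquant.pipeline`,
  `cmquant.cli`): CSV traces and multi-page TIFF images with JSON
  sidecars, a config-driven simulate→analyze→compare driver with a
  deterministic provenance manifest.

## CLI

```sh
# simulate a cohort of voltage-clamp families
cmquant simulate --modality na --n-cells 20 --seed 1 --noise-sd 0.02 --out data/

# analyze traces (na + inact families in one directory)
cmquant analyze-na --in data/ --out results.csv [--vrev 65]
cmquant analyze-ap --in data/ --out results.csv
cmquant analyze-ca --in data/ --out results.csv
cmquant analyze-image --in data/ --lines lines.json --out results.csv

# two-group comparison of a results table
cmquant compare --in results.csv --groups donor,R1267Q --out stats.csv

# full pipeline from a YAML/JSON config
cmquant run-all --config config.yaml --seed 1 --out out/
```

Exit codes: 0 ok, 1 partial failure, 2 configuration error. A minimal
`run-all` config:

```yaml
seed: 1
n_cells: 20
modalities: [na, inact, ap, ca, image]
groups:
  - label: donor
  - label: R1267Q
    gating: {v_half_act: -30.0, g_max: 11.0}
```

## Notes

Absolute gating/AP/transient preset values are plausible invented
defaults; only the inter-group shifts and effect directions are
meaningful. Time constants: the activation gate uses a bell-shaped
voltage-dependent tau centered on its midpoint; the inactivation tau is
voltage-independent so rigid midpoint translations propagate exactly into
the fitted curves.
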