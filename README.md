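# somatomap

Single-subject somatotopic mapping of fingertip representations from fMRI,
implemented as a tested, reusable pipeline with a synthetic-data generator so
every stage can be validated without scanner data.

The analysis chain:

1. **Traveling-wave localizer** — combine forward/reverse phase-encoding
   runs, fit the stimulation-frequency sinusoid per voxel (amplitude, phase,
   coherence), define five fingertip ROIs from 2π/5 phase bins above a
   coherence threshold (default 0.25), and expand them into the analysis
   volume (within 5 voxels of any ROI, inside the brain).
2. **Event-related GLM** — 1 s boxcars convolved with a canonical
   double-gamma HRF and its orthogonalized temporal derivative (10 task
   regressors); two-step fit: OLS with default timing (6 s / 16 s peaks),
   per-subject peak-latency estimation from the ROI-mean fitted HRFs, then
   GLS prewhitened with Tukey-tapered noise autocorrelations estimated from
   20×20 in-slice residual tiles. One-sided t-tests per fingertip.
3. **FIR deconvolution** — 13 time-shifted regressors per fingertip
   (0–12 TRs) for nonparametric HRF shape estimates.
4. **Adaptive multiple testing** — least-squares estimation of the true-null
   count, adaptive step-down (Holm) FWE and adaptive step-up FDR adjustment
   within the analysis volume, Hommel adjustment for small test families,
   and conversion of adjusted p-values to Z.
5. **Overlap statistics** — activation masks, exactly-k overlap counts and
   threshold sweeps, adjacent-pair overlap ratios (intersection over the
   mean activation count), anterior/posterior ROI division, ROI-averaged
   response tables with cross-subject normalization.
6. **Vein mapping** — Laplacian phase unwrapping, Gaussian high-pass,
   thresholding plus 2 mm spherical dilation, and 0.5 mm proximity
   classification.
7. **Surface utilities** — mesh Dijkstra distances between ROI centers of
   mass, cortical-depth maximum-intensity and complex-phase projections,
   additive RGBA blending for overlay maps.

The `synthetic_data` module generates ground-truthed phantoms: five
somatotopically ordered finger bands with narrow anterior and broad
posterior tuning (plus a far-posterior zone responsive to all fingers that
the localizer cannot see), block-constrained event-related paradigms, cyclic
phase-encoding paradigms, a linear BOLD forward model with AR(1) noise and
slow drift, and wrapped phase volumes with vein-like features.

## Tests

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: report-table
arithmetic, GLS/FWE/FDR calibration, exact FIR and timing recovery, the
anterior-vs-posterior overlap gradient over 100 seeded end-to-end phantom
replicates, and oracle equivalence against reference implementations.
The full suite takes a few minutes on one CPU.

## CLI

All commands take a YAML study configuration (see
`somatomap.pipeline.StudyConfig` for fields and defaults; every
paper-derived threshold is named there and overridable):

```
somatomap simulate  --config study.yaml   # write phantom, masks, event tables
somatomap localizer --config study.yaml   # coherence/phase maps + ROI counts
somatomap er        --config study.yaml   # GLM stage, t and Z maps
somatomap veins     --config study.yaml [--fwhm-mm F --threshold-rad T --dilate-mm D]
somatomap report    --config study.yaml   # four report tables (TSV)
somatomap all       --config study.yaml   # full study end to end
somatomap mt-adjust p.txt --method {holm-adaptive,fdr-adaptive,hommel} --out adj.txt
```

Volumes are written as NIfTI-1, tables as tab-separated text.

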