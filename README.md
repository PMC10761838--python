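# specdiv

Hyperspectral tree-species mapping and community-diversity analysis on
synthetic landscapes.

The package implements a full field-plus-imaging-spectroscopy analysis chain:

1. **`specdiv.synthgen`** — seeded synthetic landscapes: species pools with
   spectral signatures and climate niches, gridded climate covariates across
   protected areas (PAs), hyperspectral scenes (425 bands, 4 m pixels) with
   crown-level ground truth, and field quadrat surveys.
2. **`specdiv.spectral`** — band management (noisy/water-absorption band
   removal, four classification regions), brightness normalization (unit
   Euclidean norm), minimum-noise-fraction transform, NDVI masking, canopy
   indices (NDVI, CCI, NIRv, NIRvP, NDWI).
3. **`specdiv.classify`** — crown-spectra training sets, 75/25 per-class
   splits, SMOTE balancing, OOB-tuned random forests, per-pixel species maps,
   confusion-matrix accuracy reports (overall accuracy, kappa, producer's and
   user's accuracies).
4. **`specdiv.gridding`** — 0.005° grid overlay, 0.5 ha plot extraction with a
   70% forest-cover rule, pixel-to-abundance extrapolation via canopy spread,
   covariate attachment.
5. **`specdiv.scglr`** — supervised-component Poisson regression of the cell ×
   species abundance matrix on climate covariates, with Ward spatial blocks
   and leave-one-block-out cross-validation (pooled per-species Spearman).
6. **`specdiv.community`** — correspondence analysis, supplementary projection
   of predicted abundances, Ward assemblage typing with bootstrap uncertainty,
   Sørensen between-type similarity.
7. **`specdiv.functional`** — trait tables (wood density, phenology, max DBH,
   CCI/NIRvP/NDWI with central-95% trimming), community-weighted means,
   convex-hull functional richness (FRic) and functional divergence (FDiv).
8. **`specdiv.darkdiv`** — Beals-smoothing co-occurrence probabilities,
   species-specific 5% quantile thresholds, dark-diversity membership and
   summaries.
9. **`specdiv.pipeline` / `specdiv.cli`** — configuration-driven orchestration
   with checksummed run manifests and output-schema validation.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact oracles
(Beals brute force, convex-hull volumes, CA χ² identity, hand confusion
matrices) and simulation floors (classification accuracy ≥ 90%, gradient
recovery |ρ| ≥ 0.9, spatial-CV median ρ ≥ 0.6, dark-diversity injection
recovery ≥ 80%, pipeline determinism).

## CLI

```bash
specdiv all --out runs/demo --seed 0            # full demo run
specdiv classify --config my_run.yaml           # run up to the classify stage
specdiv validate runs/demo                      # schema/invariant checks
```

Every run writes `config.yaml` (the effective configuration) and
`manifest.json` (SHA-256 checksums, timings and warnings per stage) next to
the CSV/JSON/NPY artifacts; reruns with the same config reproduce identical
checksums.

The same flow is available programmatically:

```python
from specdiv.pipeline import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(out_dir="runs/demo", seed=0))
```

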