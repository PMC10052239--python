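# multimsi

Correlative chemical imaging toolkit: aligns multimodal mass-spectrometry-
imaging (MSI) blocks and hyperspectral fluorescence microscopy into a single
pixel-indexed multimodal matrix, decomposes it into globally joint, locally
joint and unique spatial-chemical components (OnPLS-style multiblock
modeling), and predicts ion distributions at microscopy resolution through
VIP-gated, PLS-based image fusion.

## What's inside

| Module | Purpose |
| --- | --- |
| `multimsi.cube` | `SpectralImageCube`, black/data pixel partitioning, pixel-matrix flattening and score-image restoration |
| `multimsi.imaging_io` | imzML 1.1 read/write (continuous + processed), multi-channel TIFF lambda stacks, masks, CSV export |
| `multimsi.preprocess` | rolling-minimum baseline correction, per-spectrum RMS normalization, peak-region extraction, ROI subsetting |
| `multimsi.transform` | composable/invertible 2D affines and identical per-channel resampling (nearest/linear/bicubic) |
| `multimsi.metrics` | MSE, multi-class Jaccard (8-bit quantized), entropy / joint entropy / mutual information in bits, SSIM |
| `multimsi.registration` | PCA reference images, least-squares control-point affine, Mattes MI, 1+1-evolutionary refinement, exhaustive optimizer-parameter search |
| `multimsi.chemometrics` | multimodal assembly, centering/scaling, PCA, OnPLS-style global/local/unique decomposition, 7-fold venetian-blind component advice |
| `multimsi.fusion` | OPLS (X = MSI blocks, Y = hyperspectral channels), VIP scores and selection, per-ion PLS fusion with reconstruction scores, residual and 95% CI images |
| `multimsi.phantom` | synthetic trimodal phantoms with plaque-like features, planted joint/unique structure, known misalignments and full ground truth |
| `multimsi.pipeline` / `multimsi.cli` | end-to-end orchestration with config provenance, seeding and resume |

## CLI

```bash
multimsi simulate  --spec spec.yaml --seed 0 --out fixtures/
multimsi register  --fixed a.imzML --moving b.imzML --points pts.csv \
                   --interp bicubic --seed 0 --out transform.json
multimsi metrics   --a img1.tiff --b img2.tiff --out metrics.json
multimsi decompose --blocks neg.imzML pos.imzML pep.imzML \
                   --global 1 --local "1,2:1" --unique "1:1" --out model/
multimsi fuse      --msi neg.imzML --microscopy lambda.tiff \
                   --transform transform.json --vip-threshold 1.0 --out fusion/
multimsi run       --config run.yaml
```

Control-point CSV files use the header `fixed_x,fixed_y,moving_x,moving_y`.
Pipeline configs are YAML mirrors of `multimsi.pipeline.PipelineConfig`;
the effective config and its hash are written next to the outputs and a
completed run resumes without recomputation.

## Conventions

- Grids are row-major, 0-based, pixel centers; points are (x, y) =
  (column, row); imzML 1-based coordinates are shifted on read.
- A pixel is *black* iff its summed spectrum is exactly zero; only data
  pixels enter modeling, and score images reinstate black pixels as
  background without interpolation.
- All entropies and mutual information are reported in bits; histogram
  metrics quantize image pairs to 8 bits with joint min-max scaling.
- Every stochastic routine takes an explicit seed; equal seeds give
  bit-identical results.
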