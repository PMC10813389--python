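# cecounter

Semi-supervised U-Net pipeline for detecting cell centers in phase-contrast
images of cultured cell monolayers and converting the detections into cell
density (cells·mm⁻²) and total-cell-number estimates for a culture vessel.

Because no public image set exists for this task, the package ships a
synthetic generator that renders phase-contrast-like Voronoi monolayers with
exactly known cell centers at low / middle / high density regimes; every
downstream stage is developed and evaluated against it.

Pipeline:

1. **synthetic** – Voronoi-mosaic monolayer renderer (Poisson cell counts,
   minimum-spacing placement, dark boundaries, halo, noise) + dataset writer.
2. **dataset_io** – images, center-annotation CSVs, train/val/test splits.
3. **preprocess** – ¼ area-interpolation resize, gamma, percentile contrast
   stretch, unsharp boundary highlighting, histogram equalization; flip-based
   ×2 / ×4 augmentation with exact coordinate remapping.
4. **unet** – two-class U-Net implemented directly on NumPy (im2col
   convolutions, manual backprop, Adam); same-padding so probability maps
   align with input pixels; disk rasterization of point labels.
5. **trainer** – supervised training with epoch selection by validation-loss
   argmin, plus the two-stage semi-supervised workflow: an *initial model*
   trained on the labeled pool pseudo-labels the unlabeled pool, a simulated
   manual-correction step revises the pseudo-labels, and the merged pool
   (re-split 2341:757, augmented ×4) trains the *cell count model*.
6. **detection** – probability map → thresholded connected components →
   sub-pixel weighted centroids.
7. **evaluator** – greedy nearest-first one-to-one point matching, per-image
   precision / recall / F macro-averaged with bootstrap 95% CIs, density
   correlation.
8. **quantify** – field density and extrapolation to vessel growth area.
9. **cli** – file-mediated subcommands wiring it all together.

The network is pure NumPy because no deep-learning framework is available in
the target environment; the models used here are small (depth 2–3) and train
in minutes on one CPU. Gradients are verified against finite differences in
the test suite.

## CLI

```bash
cecounter simulate --n-images 60 --mix low=0.34,middle=0.33,high=0.33 \
    --out data/train --seed 0
cecounter preprocess --in data/train --out data/train_pp --config config.yaml
cecounter train --stage full --config config.yaml --out runs/exp1
cecounter predict --weights runs/exp1/cellcount.npz --in data/test --out pred/
cecounter detect --pmaps pred/ --out centers/
cecounter evaluate --pred centers/ --ref data/test/annotations \
    --radius 10 --out report.json
cecounter count --centers centers/ --geometry geom.yaml --vessel well_6 \
    --out totals.csv
cecounter full-pipeline --config config.yaml --out runs/full --seed 1
```

`full-pipeline` simulates the three pools, preprocesses, runs the two-stage
training, evaluates both models on the held-out test pool, and writes
checkpoints, loss curves (`epoch,train_loss,val_loss` CSVs) and a single
`report.json`. A minimal config:

```yaml
seed: 1
simulate: {n_labeled: 54, n_unlabeled: 72, n_test: 36,
           width_px: 128, height_px: 128, um_per_px: 2.0}
preprocess: {resize_factor: 1.0}
model: {depth: 2, base_channels: 8}
train: {max_epochs: 9, lr: 0.0015, batch_size: 4, crop_size: 64,
        fg_weight: 4.0, disk_radius_px: 2}
detect: {}
eval: {match_radius_px: 4.0, bootstrap_reps: 500}
quantify: {vessel_type: well_6}
correction: {p_fix_miss: 1.0, p_fix_spurious: 1.0, jitter_px: 0.0}
```

## Conventions

Coordinates are 0-based (x = column, y = row), sub-pixel floats. Annotation
CSVs have header `image_id,x,y`; split files are JSON with `train/val/test`
id lists; images are 8-bit grayscale PNG/TIFF. One seed governs every
stochastic stage.
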