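# beadquant

Quantitative phenotyping of dendritic **beading** in the *C. elegans* PVD
neuron from fluorescence microscopy images.

PVD is a multidendritic nociceptor whose stereotyped, menorah-like arbor
degenerates with age and after acute cold-shock: bubble-like protrusions
("beads") appear along the dendrites.  Counting and measuring these beads by
eye is slow and biased, and classical intensity thresholding cannot separate
beads from the autofluorescent lipid droplets that overlap the dendrites in
maximum projections.  `beadquant` implements the downstream analysis stack a
lab needs around an instance-segmentation model:

- **Tiling / stitching** (`beadquant.tiling`): 2048 x 2048 projections are
  split into 9 overlapping 1024-px tiles (stride 512, mirror padding for
  non-conforming sizes).  Per-tile instance predictions are merged back in
  raster order: an instance is kept iff its score `s > 0.7` and its overlap
  with every already-kept mask is at most 30% of its own area.
- **Segmentation backends** (`beadquant.backends`): a pluggable per-tile
  contract `segment_tile(tile, spec) -> [InstanceMask]`, with a noisy
  ground-truth *oracle* (configurable false-negative / false-positive /
  boundary-perturbation rates) for validating every downstream stage, a
  Laplacian-of-Gaussian *blob* baseline for real images, and a recorded
  configuration schema for an external Mask R-CNN-style CNN backend.
- **Evaluation** (`beadquant.evaluation`): greedy one-to-one IoU matching;
  precision = TP/(TP+FP), recall = TP/(TP+FN), per-bead Jaccard
  J = |A ∩ B| / |A ∪ B|; low/high bead-count stratified summaries and a
  droplet-rejection rate for the confounders.
- **46-metric profile** (`beadquant.features`): per image, bead count, total
  and per-bead areas, nearest-neighbor and all-pairwise inter-bead centroid
  distances, per-bead mean-intensity statistics, and shape summaries — e.g.
  m16 = fraction of beads with area < 100 px, m17 = mean pairwise inter-bead
  distance, m37 = 90th percentile of bead intensity.
- **Classification** (`beadquant.classify`): predicts biological status
  (young vs aged, cold-shocked vs control, ...) from the 46 metrics with a
  random-subspace discriminant ensemble (an sklearn-compatible estimator),
  linear SVM, logistic regression and KNN under stratified 5-fold CV, plus
  correlation-based PCA, ROC/AUC, and bidirectional AIC stepwise logistic
  feature selection.
- **Synthetic scenes** (`beadquant.synthetic`): a generator for PVD-like
  scenes — menorah arbor, on-dendrite beads, off-dendrite droplet
  confounders, Gaussian PSF, Poisson + Gaussian noise — with exact instance
  ground truth, so the whole pipeline is testable without the original
  images.  Shipped condition profiles reproduce the qualitative biology:
  aged animals carry more, slightly smaller beads spread evenly over the
  arbor (mean inter-bead distance falls), cold-shocked animals grow beads on
  distal 3rd/4th-order branches (mean inter-bead distance rises).

## Worked example

```python
from beadquant import synthetic, backends, evaluation, features

scene = synthetic.generate_scene(synthetic.DEFAULT_PROFILES["aged"],
                                 shape=(1024, 1024), seed=3)
pred = backends.segment_image(scene.rendered,
                              backends.OracleBackend(scene.truth,
                                  backends.OracleNoise(drop_rate=0.1,
                                      spurious_rate=0.5, dilate_px=1,
                                      score_dist=(0.9, 0.03))),
                              tile=512, stride=256)
sc = evaluation.evaluate_pair(pred, scene.truth)
vec = features.profile_image(scene.rendered, pred)
print(f"truth beads {len(scene.truth)}  predicted {len(pred)}")
print(f"precision {sc.precision:.3f}  recall {sc.recall:.3f}  "
      f"mean Jaccard {sc.mean_jaccard:.3f}")
print(f"m01 (count) {vec['m01']:.0f}  m17 (mean inter-bead px) {vec['m17']:.1f}")
```

prints

```
truth beads 79  predicted 78
precision 0.936  recall 0.924  mean Jaccard 0.764
m01 (count) 78  m17 (mean inter-bead px) 478.1
```

i.e. the oracle configured with a 10% miss rate and ~0.5 spurious blobs per
tile comes back, after stitching and merging, with recall ≈ 0.9, precision
≈ 0.93 and a per-bead Jaccard pulled below 1 by the 1-px boundary
perturbation — exactly the noise budget that was dialed in.

The same stages run from the shell:

```bash
beadquant simulate --condition aged --n-images 5 --seed 1 --out-dir sim/
beadquant segment  --image-dir sim/ --backend oracle --truth-dir sim/ --out-dir pred/
beadquant evaluate --pred-dir pred/ --truth-dir sim/ --out eval.csv
beadquant profile  --image-dir sim/ --mask-dir pred/ --out features.csv
beadquant classify --features-csv features.csv --label-column condition --out report.json
beadquant run-all  --seed 1 --out run/          # the whole pipeline
```

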