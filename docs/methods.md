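# Methods

This note documents the models, conventions and numerical choices behind
`beadquant`, and what its synthetic substrate does and does not show about
real imaging data.

## Problem setting

The PVD neuron's dendritic arbor is imaged as single-channel maximum
projections (nominally 2048 x 2048 px, 8/16-bit).  Neurodegeneration
manifests as bubble-like beads along the dendrites; an instance segmenter
outputs one binary mask per bead, and the analysis reduces each image to a
46-metric morphological profile used for group comparisons and for
predicting biological status (young / aged / cold-shocked).  All geometry is
in pixels — the imaging carries no micron calibration — with 0-based,
row-major coordinates and the origin at top-left.

## Tiling and stitch/merge

Large frames are cut into square tiles of side `tile` (default 1024) on a
regular grid with stride `stride` (default 512 = tile/2, the only grid that
yields the canonical 9 tiles for a 2048-px frame with no padding).  Per
axis, `n = max(1, ceil((dim - tile)/stride) + 1)` positions at multiples of
the stride; the frame is mirror-padded to `stride*(n-1) + tile`, the pad
split symmetrically with the extra pixel going bottom/right.  Mirror
reflection is repeated when the pad exceeds the source extent, so degenerate
frames (even 1 x 1) still tile.

Stitching visits tiles top-left to bottom-right and, within a tile,
candidates by descending score (ties by ascending label).  A candidate is
dropped when `score <= 0.7` (strictly greater keeps) and suppressed when its
intersection with any already-kept mask exceeds 30% of the **candidate's
own** area (exactly 30% keeps).  The overlap denominator is the candidate
mask because the rule exists to discard re-detections of an already-kept
object in a later overlapping tile; duplicates are suppressed, never fused.
Masks are mapped back to source coordinates by removing the pad and clipping
to the frame; instances empty after clipping are discarded.  Stitching an
already-merged result is a no-op (idempotence), which the tests check.

Training-set bookkeeping for a CNN backend is pure arithmetic exposed as
functions: 19 full frames x 9 tiles = 171 training tiles, a 20% holdout
(floor) of 34 tiles, and inline augmentation over 420 epochs (20 head-only +
400 full-model) giving an effective set of (171 - 34) x 420 = 57,540
samples.  The CNN itself (a Mask R-CNN-style network) is deliberately not
part of this package; `MASK_RCNN_CONFIG` records the training schema and any
model satisfying the tile contract plugs into `segment_image`.

## Segmentation backends

**Oracle.**  For validating everything downstream of a segmenter, the
oracle serves ground truth corrupted by configured rates: per-instance
omission probability `drop_rate` (false negatives), Poisson-rate
`spurious_rate` spurious discs per tile placed at least 5 px from all truth
masks (false positives, unambiguous accounting), boundary
dilation/erosion `dilate_px`, and Gaussian scores clipped to [0, 1].  All
decisions for a truth instance are keyed on (seed, label), so a bead visible
in several overlapping tiles is consistently kept or dropped and the
realized miss fraction is exactly binomial in the instance count.  A tile
only serves instances lying entirely inside it; re-detections in
neighboring tiles are removed by the stitcher's overlap rule.

**Blob baseline.**  A classical intensity-only baseline: normalized
Laplacian-of-Gaussian blob candidates (sigma 3-9, response threshold 0.10),
grown to the connected half-peak region above the tile median, gated to
[20, 2000] px area, scored by normalized contrast.  An optional gate keeps
only blobs within `dendrite_proximity_px` of a ridge-detected (Sato filter,
Otsu threshold) dendrite skeleton, which rejects off-dendrite droplets.
This baseline exists to quantify, on synthetic scenes, how far intensity
thresholding falls short of an instance segmenter — it has no access to
shape/context cues and confuses bright droplets near dendrites with beads.

## Evaluation

Predicted and truth instances are matched one-to-one by greedy
intersection-over-union: all cross IoUs are computed, pairs accepted in
descending IoU (ties by ascending pred then truth label) while both sides
are free and IoU >= `iou_min` (default 0.3, safely below the per-bead
Jaccard an adequate segmenter achieves).  Precision = TP/(TP+FP),
recall = TP/(TP+FN); with no predictions, precision is NaN-flagged rather
than forced to a value.  Greedy matching is verified against a brute-force
optimal assignment on all small fixtures.  Because "true negatives" are
well-defined only when confounders are known, droplet handling is reported
as a rejection rate — the fraction of placed droplets whose center no
predicted mask covers.  Population reports stratify images into low (< 100)
and high (>= 100) truth-bead-count groups, mean +/- SEM.

## The 46-metric profile

One `BeadRecord` per instance (intensities from the raw, un-normalized
image; geometry from the mask), reduced to 46 slots: count and total area;
area distribution (mean, SEM, min/max, percentiles, histogram fractions in
[0,50), [50,100), [100,200), [200,400), [400,inf), fraction < 100 px, SD,
CV); nearest-neighbor and all-pairwise centroid distance statistics (mean,
median, SD, SEM, percentiles, fractions < 150 px and < 300 px, CV);
per-bead mean-intensity statistics; mean eccentricity and solidity; total
integrated intensity.  "Bead intensity" always denotes the distribution
over beads of each bead's mean intensity, so its SD (m35) is literally the
standard deviation of mean bead intensity.

Pinned numerical conventions: percentiles interpolate linearly between
order statistics; SD uses ddof = 1 and is defined as 0 when only one value
exists (hence the 2-bead worked fixture has SEM of pairwise distance = 0);
SEM = SD/sqrt(n); inter-bead distances are centroid Euclidean distances
over all C(n,2) unordered pairs; no background subtraction.  Metrics
needing >= 1 bead (area/intensity/shape) or >= 2 beads (distances) are
NaN-flagged undefined otherwise and excluded from group means and from each
metric's reported n.  The Bonferroni helper returns both the exact
family_alpha/n and a floor-truncated 3-decimal display value (0.05 over 3
comparisons displays as 0.016).

## Synthetic scenes

The generator emulates the study substrate, not its optics.  An arbor has
one horizontal primary dendrite near mid-height; each menorah contributes a
long order-2 stem (0.33 x frame height, alternating dorsal/ventral as in
real PVD), two short order-3 arms at the stem tip (half-width 3% of the
frame) and short order-4 risers (2.5% height) continuing away from the
primary.  With this geometry the distal orders hold little of the arbor's
total length but sit far from the primary, which is what makes the
condition contrasts emerge from placement alone.

Beads: per-image count ~ N(mean, sd) clamped at 0; branch order from the
profile's order weights (`None` = uniform per unit skeleton length);
position uniform along segments of that order with <= 2 px perpendicular
jitter; radius set so the half-peak disc area matches an area draw
(area = pi r^2, clamped >= 20 px).  Droplets take the same radius
distribution but are rejection-sampled >= 10 px from the skeleton and never
enter the ground truth.  Rendering: anti-aliased dendrite polylines
(max-composited, intensity 160), radially symmetric blobs whose half-peak
contour sits at the bead radius (peak ~ N(300, 50) clipped), Gaussian PSF
(sigma 1.2 px), constant background 100, Poisson shot noise (1 photon per
intensity unit; 0 disables) plus Gaussian read noise (sd 2).  Truth masks
are the pre-noise half-peak supports — the discs of each bead's radius —
with overlapping discs merged (union-find) into a single instance so truth
instances stay disjoint.

Default profiles (count mean +/- sd, area mean +/- sd px, order weights):
young (30 +/- 10, 150 +/- 40, uniform over orders); aged (100 +/- 25,
120 +/- 35, uniform per unit length — beads "evenly throughout" the arbor);
cold-shock (70 +/- 20, 150 +/- 40, weights (0.05, 0.15, 0.40, 0.40) biased
to distal branches).  Interpreting the aged profile as length-uniform
rather than order-uniform is deliberate: the mean pairwise distance of
i.i.d. placements does not depend on the count, so the aged-vs-young
spread contrast must come from *where* beads sit — equal per-order weights
overweight the short distal orders relative to length-uniform placement,
making young relatively distal-heavy and aged relatively proximal.  With the
geometry above this yields, by construction and verified by Monte-Carlo:
aged count >> young count; aged mean inter-bead distance < young; cold-shock
mean inter-bead distance > a count-matched length-uniform control.  These
contrasts are properties of the shipped defaults, frozen at design time.

What passing tests on this substrate show: the tiling, merge rules,
matching, metric definitions and classifiers behave correctly and
reproducibly under known ground truth with realistic scales (tens to ~150
beads of ~150 px on a 2048-scale arbor, droplet confounders).  What they do
not show: performance of any real segmenter on real images — fluorophore
texture, body autofluorescence beyond discrete droplets, arbor
disorganization, z-projection artifacts and optical aberrations are not
modeled, and the study's own images are not redistributable.  Classifier
accuracies on synthetic populations (~100%) therefore overstate what the
harder real separations (~80-90%) allow; they validate the machinery, not
the biology.

## Classification

All 46 metrics enter every model.  Undefined entries are median-imputed and
features standardized, both learned on training folds only (sklearn
pipelines).  The subspace discriminant ensemble draws B = 30 random feature
subspaces of dimension ceil(46/2) = 23, fits a linear discriminant
(lsqr solver) on each — refitting with Ledoit-Wolf ridge shrinkage when the
within-class covariance is singular, never dropping a learner — and
aggregates by averaging posterior probabilities (a probability-weighted
vote; with B = 1 and a full subspace it reduces exactly to LDA).  SVM is
linear with C = 1; logistic regression and KNN (k = 5, Euclidean) complete
the four families.  Cross-validation is stratified 5-fold with shuffling
under the run seed; ROC curves sweep the model's continuous score and AUC
uses the trapezoidal rule (equal to the normalized Mann-Whitney U
statistic, which the tests verify exactly).  PCA is correlation-based
(standardized features, zero-variance columns dropped with a warning).

Stepwise logistic selection starts from the intercept-only model and at
each step takes the single addition or removal that most lowers AIC,
stopping when neither helps.  AIC with 46 candidates scanned per step is a
liberal criterion: on pure-noise labels it admits on the order of ten
spurious metrics (the best-of-46 chi-square exceeds the AIC penalty of 2
easily), while planted informative metrics enter first and are recovered
essentially always.  The selection is therefore read as a ranking of entry
order, not as a sparse certificate.

## Pipeline and determinism

`run_pipeline` executes simulate -> segment -> evaluate -> profile ->
classify, writing images, labeled-mask files (16-bit label image + JSON
sidecar with scores; colliding instances stored as run-length records so
round-trips are lossless), per-image evaluation CSV, the 46-column feature
CSV, group summaries and a classification report, plus a manifest with the
config snapshot, its hash and per-stage counters (instances kept, dropped
by score, dropped by overlap — making the merge rules auditable).  Every
random draw derives from the configured seed via seed sequences, so a rerun
with the same config reproduces byte-identical CSV/JSON; a matching config
hash lets a rerun reuse simulation/segmentation artifacts on disk.

## Problem sizes

Tests and the acceptance script run scenes at 512-1024 px frames (2048 only
for tile-count bookkeeping), 30 seeds per Monte-Carlo arm, 60 images per
class for classification, and at least 1000 beads for rate-calibration
checks with 3-sigma binomial/Poisson bands — sizes at which every
statistical assertion has comfortable power while the whole suite runs in a
few minutes on one CPU.

## Known limitations

- The exact composition of the original 46-metric list is only partially
  anchored by named indices; unnamed slots are filled with the same
  statistic families and documented above, so profiles are internally
  consistent but not guaranteed slot-for-slot identical to other
  implementations.
- Contrast normalization defaults to 1%/1% quantile saturation; the
  upstream convention it mirrors does not pin these fractions.
- Greedy IoU matching can differ from the optimal assignment on pathological
  overlap patterns; equality is guaranteed (and tested) only for
  well-separated detections.
- The dendrite-proximity gate of the blob baseline depends on ridge
  detection and will pass droplets lying within the gate distance of a
  dendrite.
- Branch order is known for synthetic beads only; no metric infers it from
  masks.
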