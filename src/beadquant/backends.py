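"""Pluggable per-tile instance segmenters.

Three backends conform to the tile contract
``segment_tile(tile_image, tile_spec) -> list[InstanceMask]`` (masks in
tile coordinates, scores attached):

* :class:`OracleBackend` - a configurable noisy ground-truth oracle used to
  manufacture true/false positives and negatives on demand for testing the
  stitching, evaluation and profiling stages;
* :class:`BlobBackend` - a classical Laplacian-of-Gaussian baseline for
  real images (intensity-only segmentation, the approach a CNN replaces);
* a documented configuration schema for an external Mask R-CNN-style CNN
  backend (:data:`MASK_RCNN_CONFIG`); the network itself is out of scope
  here and plugs in through the same contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.filters import sato, threshold_otsu

from .core_io import FluorescenceImage, InstanceMask, SegmentationResult
from .errors import BackendContractError
from .tiling import TileSpec, extract_tiles, plan_tiles, stitch_and_merge

#: Recorded training configuration schema for a CNN (Mask R-CNN-style)
#: backend: transfer learning from ImageNet weights, a short head-only
#: phase then full-model training, inline flip/rotation/shear
#: augmentation, a 20% tile holdout for validation-loss checkpointing,
#: and the production score threshold.  Training such a network is GPU
#: work outside this package; any trained model conforming to the tile
#: contract plugs into :func:`segment_image`.
MASK_RCNN_CONFIG = {
    "architecture": "mask-rcnn/resnet101-fpn",
    "pretrained": "imagenet",
    "epochs_head": 20,
    "epochs_full": 400,
    "holdout_frac": 0.20,
    "augmentations": ["fliplr", "flipud", "rot90", "shear"],
    "tile": 1024,
    "stride": 512,
    "score_min": 0.7,
    "overlap_max": 0.30,
}


def training_tile_count(n_images: int, shape=(2048, 2048), tile: int = 1024, stride: int = 512) -> int:
    """Number of training tiles produced by tiling ``n_images`` frames."""
    _, specs = plan_tiles(shape, tile=tile, stride=stride)
    return n_images * len(specs)


def holdout_split(n_tiles: int, holdout_frac: float = 0.20) -> tuple[int, int]:
    """(train, holdout) tile counts for a fractional holdout (floor)."""
    n_holdout = int(n_tiles * holdout_frac)
    return n_tiles - n_holdout, n_holdout


def effective_training_size(n_train_tiles: int, epochs: int) -> int:
    """Effective augmented set size when augmentation is drawn inline:
    every epoch re-draws each tile, so tiles x epochs distinct samples."""
    return n_train_tiles * epochs


# ---------------------------------------------------------------------------
# oracle backend


@dataclass(frozen=True)
class OracleNoise:
    """Controlled corruption of the ground truth.

    ``drop_rate`` is the per-instance omission probability (the false
    negative source); ``spurious_rate`` the expected spurious blobs per
    tile (false positive source); ``dilate_px`` perturbs mask boundaries
    (negative erodes); scores are Gaussian draws clipped to [0, 1].  All
    decisions are deterministic given ``seed``: drop/dilate/score for a
    truth instance depend only on (seed, label), so a bead visible in
    several overlapping tiles is consistently kept or dropped.
    """

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    dilate_px: int = 0
    score_dist: tuple[float, float] = (1.0, 0.0)
    seed: int = 0


class OracleBackend:
    """Serves (noisy) ground truth for the tile it is asked about.

    Only truth instances lying entirely inside a tile are emitted for that
    tile; duplicates across overlapping tiles are suppressed downstream by
    the stitcher's overlap rule.
    """

    name = "oracle"

    def __init__(self, truth: SegmentationResult, noise: OracleNoise | None = None) -> None:
        self.truth = truth
        self.noise = noise or OracleNoise()
        self._tile_counter = 0

    def segment_tile(self, tile_image: np.ndarray, spec: TileSpec) -> list[InstanceMask]:
        tile_index = self._tile_counter
        self._tile_counter += 1
        h, w = self.truth.source_shape
        top, _, left, _ = spec.pad
        # tile window in source coordinates
        tr0 = spec.origin[0] - top
        tc0 = spec.origin[1] - left
        tr1, tc1 = tr0 + spec.size, tc0 + spec.size
        in_tile = [
            inst
            for inst in self.truth.instances
            if inst.bbox[0] >= tr0 and inst.bbox[1] <= tr1 and inst.bbox[2] >= tc0 and inst.bbox[3] <= tc1
        ]
        shifted = [
            InstanceMask(
                shape=(spec.size, spec.size),
                bbox=(
                    inst.bbox[0] - tr0,
                    inst.bbox[1] - tr0,
                    inst.bbox[2] - tc0,
                    inst.bbox[3] - tc0,
                ),
                crop=inst.crop,
                score=inst.score,
                label_id=inst.label_id,
            )
            for inst in in_tile
        ]
        return oracle_segment((spec.size, spec.size), shifted, self.noise, tile_index=tile_index)


def oracle_segment(
    tile_shape: tuple[int, int],
    truth_in_tile: list[InstanceMask],
    noise: OracleNoise,
    tile_index: int = 0,
) -> list[InstanceMask]:
    """Corrupt per-tile truth according to the configured noise."""
    out: list[InstanceMask] = []
    th, tw = tile_shape
    for inst in truth_in_tile:
        rng = np.random.default_rng([noise.seed, inst.label_id])
        if rng.uniform() < noise.drop_rate:
            continue
        crop, bbox = inst.crop, inst.bbox
        if noise.dilate_px != 0:
            n = abs(noise.dilate_px)
            if noise.dilate_px > 0:
                padded = np.pad(crop, n)
                grown = ndimage.binary_dilation(padded, iterations=n)
                r0 = max(bbox[0] - n, 0)
                c0 = max(bbox[2] - n, 0)
                r1 = min(bbox[1] + n, th)
                c1 = min(bbox[3] + n, tw)
                grown = grown[
                    n - (bbox[0] - r0) : padded.shape[0] - (n - (r1 - bbox[1])),
                    n - (bbox[2] - c0) : padded.shape[1] - (n - (c1 - bbox[3])),
                ]
                crop, bbox = grown, (r0, r1, c0, c1)
            else:
                crop = ndimage.binary_erosion(crop, iterations=n)
                if not crop.any():
                    continue
        score = float(np.clip(rng.normal(*noise.score_dist), 0.0, 1.0))
        out.append(InstanceMask(shape=tile_shape, bbox=bbox, crop=crop, score=score, label_id=inst.label_id))
    # spurious detections, placed >= 5 px from all truth masks so that
    # FP/FN accounting stays unambiguous
    rng_tile = np.random.default_rng([noise.seed, 1_000_003 + tile_index])
    n_spurious = int(rng_tile.poisson(noise.spurious_rate)) if noise.spurious_rate > 0 else 0
    for j in range(n_spurious):
        for _ in range(100):
            r = float(rng_tile.uniform(8, th - 9))
            c = float(rng_tile.uniform(8, tw - 9))
            radius = max(2.0, float(rng_tile.normal(7.0, 1.0)))
            if all(_point_bbox_distance(r, c, t.bbox) >= 5.0 + radius for t in truth_in_tile):
                rr, cc = np.mgrid[
                    int(r - radius) : int(r + radius) + 1, int(c - radius) : int(c + radius) + 1
                ]
                inside = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
                inside &= (rr >= 0) & (rr < th) & (cc >= 0) & (cc < tw)
                if not inside.any():
                    continue
                mask = np.zeros(tile_shape, dtype=bool)
                mask[rr[inside], cc[inside]] = True
                score = float(np.clip(rng_tile.normal(*noise.score_dist), 0.0, 1.0))
                out.append(
                    InstanceMask(mask, score=score, label_id=900_000 + tile_index * 100 + j)
                )
                break
    return out


def _point_bbox_distance(r: float, c: float, bbox: tuple[int, int, int, int]) -> float:
    dr = max(bbox[0] - r, 0.0, r - (bbox[1] - 1))
    dc = max(bbox[2] - c, 0.0, c - (bbox[3] - 1))
    return math.hypot(dr, dc)


# ---------------------------------------------------------------------------
# classical blob baseline


@dataclass(frozen=True)
class BlobParams:
    """LoG blob baseline knobs: sigma sweep, normalized detection
    threshold, area gate in pixels, and an optional proximity gate (px)
    to a ridge-detected dendrite skeleton that rejects off-dendrite
    droplets."""

    log_sigmas: tuple[float, float] = (3.0, 9.0)
    detect_thresh: float = 0.10
    min_area: int = 20
    max_area: int = 2000
    dendrite_proximity_px: float | None = None


class BlobBackend:
    name = "blob"

    def __init__(self, params: BlobParams | None = None) -> None:
        self.params = params or BlobParams()

    def segment_tile(self, tile_image: np.ndarray, spec: TileSpec) -> list[InstanceMask]:
        return blob_baseline_segment(tile_image, self.params)


def blob_baseline_segment(tile: np.ndarray, params: BlobParams | None = None) -> list[InstanceMask]:
    """Laplacian-of-Gaussian blob candidates grown to half-peak masks.

    Candidates are thresholded on the normalized LoG response, grown to
    the connected half-peak region around their center, gated on area and
    (optionally) on proximity to a ridge-detected dendrite skeleton.  The
    score is the blob's normalized contrast above background.
    """
    params = params or BlobParams()
    tile = np.asarray(tile, dtype=np.float64)
    th, tw = tile.shape
    lo, hi = float(tile.min()), float(tile.max())
    if hi <= lo:
        return []
    norm = (tile - lo) / (hi - lo)
    blobs = blob_log(
        norm,
        min_sigma=params.log_sigmas[0],
        max_sigma=params.log_sigmas[1],
        num_sigma=5,
        threshold=params.detect_thresh,
    )
    background = float(np.median(tile))
    dendrite_dist = None
    if params.dendrite_proximity_px is not None:
        dendrite_dist = _dendrite_distance_map(norm)
    out: list[InstanceMask] = []
    label = 1
    for r, c, sigma in blobs:
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < th and 0 <= ci < tw):
            continue
        if dendrite_dist is not None and dendrite_dist[ri, ci] > params.dendrite_proximity_px:
            continue
        ext = int(math.ceil(4 * sigma * math.sqrt(2))) + 2
        r0, r1 = max(0, ri - ext), min(th, ri + ext + 1)
        c0, c1 = max(0, ci - ext), min(tw, ci + ext + 1)
        window = tile[r0:r1, c0:c1]
        peak = float(window[ri - r0, ci - c0])
        if peak <= background:
            continue
        half = background + 0.5 * (peak - background)
        above = window >= half
        lab, _ = ndimage.label(above)
        comp = lab == lab[ri - r0, ci - c0]
        area = int(comp.sum())
        if not (params.min_area <= area <= params.max_area):
            continue
        score = float(np.clip((peak - background) / (hi - background + 1e-12), 0.0, 1.0))
        mask = np.zeros((th, tw), dtype=bool)
        mask[r0:r1, c0:c1] = comp
        out.append(InstanceMask(mask, score=score, label_id=label))
        label += 1
    return out


def _dendrite_distance_map(norm: np.ndarray) -> np.ndarray:
    """Distance (px) to a ridge-detected dendrite skeleton."""
    ridge = sato(norm, sigmas=(1.0, 2.0, 3.0), black_ridges=False)
    positive = ridge[ridge > 0]
    if positive.size == 0:
        return np.full(norm.shape, np.inf)
    try:
        thresh = threshold_otsu(ridge)
    except ValueError:
        return np.full(norm.shape, np.inf)
    mask = ridge > thresh
    if not mask.any():
        return np.full(norm.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


# ---------------------------------------------------------------------------
# whole-image segmentation harness


def segment_image(
    img: FluorescenceImage,
    backend,
    tile: int = 1024,
    stride: int = 512,
    score_min: float = 0.7,
    overlap_max: float = 0.30,
) -> SegmentationResult:
    """Tile an image, run a backend per tile, validate the tile contract,
    and stitch the predictions back together."""
    plan = plan_tiles(img.shape, tile=tile, stride=stride)
    per_tile: list[tuple[TileSpec, list[InstanceMask]]] = []
    for spec, tile_img in extract_tiles(img, plan):
        try:
            masks = backend.segment_tile(tile_img, spec)
        except Exception as exc:  # attach tile context to backend failures
            raise BackendContractError(
                f"backend {getattr(backend, 'name', backend)!r} failed on tile at "
                f"origin {spec.origin}: {exc}"
            ) from exc
        for m in masks:
            if m.shape != (spec.size, spec.size):
                raise BackendContractError(
                    f"backend {getattr(backend, 'name', backend)!r} returned mask of shape "
                    f"{m.shape} for tile of size {spec.size} at origin {spec.origin}"
                )
        per_tile.append((spec, masks))
    result = stitch_and_merge(
        per_tile,
        img.shape,
        score_min=score_min,
        overlap_max=overlap_max,
        backend_name=getattr(backend, "name", "unknown"),
    )
    result.params.update({"tile": tile, "stride": stride})
    return result
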