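"""Overlapping tiling of large images and raster-order stitch/merge.

A 2048 x 2048 frame with 1024-px tiles at a 512-px stride yields the
canonical 3 x 3 = 9 overlapping tiles.  Frames that do not fit the grid
are mirror-padded symmetrically (extra pixel to the bottom/right).  When
per-tile predictions are stitched back, instances are kept only if their
score exceeds ``score_min`` (strictly) and they do not overlap any
already-kept mask by more than ``overlap_max`` of their own area, visiting
tiles top-left to bottom-right and, within a tile, by descending score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import FluorescenceImage, InstanceMask, SegmentationResult
from .errors import ParameterError

Pad = tuple[int, int, int, int]  # (top, bottom, left, right)


@dataclass(frozen=True)
class TileSpec:
    """One tile: origin (row, col) in padded coordinates, square size,
    and the pad applied to the source image."""

    origin: tuple[int, int]
    size: int
    pad: Pad


def plan_tiles(
    shape: tuple[int, int], tile: int = 1024, stride: int = 512
) -> tuple[Pad, list[TileSpec]]:
    """Plan a regular overlapping grid covering the (padded) image exactly.

    Per axis there are ``n = max(1, ceil((dim - tile)/stride) + 1)`` grid
    positions at multiples of ``stride``; the image is padded to
    ``stride*(n-1) + tile`` with the pad split symmetrically (extra pixel
    to the bottom/right).
    """
    if tile < 1 or stride < 1 or stride > tile:
        raise ParameterError("require tile >= 1 and 1 <= stride <= tile")
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1:
        raise ParameterError("image dimensions must be positive")

    def axis(dim: int) -> tuple[int, int]:
        n = max(1, math.ceil((dim - tile) / stride) + 1)
        padded = stride * (n - 1) + tile
        return n, padded - dim

    n_rows, pad_r = axis(h)
    n_cols, pad_c = axis(w)
    pad: Pad = (pad_r // 2, pad_r - pad_r // 2, pad_c // 2, pad_c - pad_c // 2)
    specs = [
        TileSpec(origin=(i * stride, j * stride), size=tile, pad=pad)
        for i in range(n_rows)
        for j in range(n_cols)
    ]
    return pad, specs


def extract_tiles(
    img: FluorescenceImage | np.ndarray, plan: tuple[Pad, list[TileSpec]]
) -> list[tuple[TileSpec, np.ndarray]]:
    """Cut the planned tiles out of the mirror-padded image."""
    arr = img.pixels if isinstance(img, FluorescenceImage) else np.asarray(img)
    pad, specs = plan
    top, bottom, left, right = pad
    padded = _pad_symmetric(arr, pad)
    out = []
    for spec in specs:
        r, c = spec.origin
        out.append((spec, padded[r : r + spec.size, c : c + spec.size]))
    return out


def _pad_symmetric(arr: np.ndarray, pad: Pad) -> np.ndarray:
    """Mirror-reflection padding; reflection is repeated when the pad
    exceeds the source extent (e.g. a 1 x 1 image padded to 4 x 4)."""
    top, bottom, left, right = pad
    if not any(pad):
        return arr
    out = arr
    while True:
        h, w = out.shape
        t, b = min(top, h), min(bottom, h)
        l, r = min(left, w), min(right, w)
        out = np.pad(out, ((t, b), (l, r)), mode="symmetric")
        top, bottom, left, right = top - t, bottom - b, left - l, right - r
        if not any((top, bottom, left, right)):
            return out


def _to_source_frame(
    inst: InstanceMask, spec: TileSpec, source_shape: tuple[int, int]
) -> InstanceMask | None:
    """Map a tile-frame instance into source coordinates; None if the mask
    is empty after removing the pad and clipping to the source frame."""
    h, w = source_shape
    top, _, left, _ = spec.pad
    # bbox in source coordinates
    r0 = inst.bbox[0] + spec.origin[0] - top
    r1 = inst.bbox[1] + spec.origin[0] - top
    c0 = inst.bbox[2] + spec.origin[1] - left
    c1 = inst.bbox[3] + spec.origin[1] - left
    cr0, cr1 = max(r0, 0), min(r1, h)
    cc0, cc1 = max(c0, 0), min(c1, w)
    if cr0 >= cr1 or cc0 >= cc1:
        return None
    crop = inst.crop[cr0 - r0 : cr1 - r0, cc0 - c0 : cc1 - c0]
    if not crop.any():
        return None
    # re-tighten the bbox after clipping
    rows = np.flatnonzero(crop.any(axis=1))
    cols = np.flatnonzero(crop.any(axis=0))
    tr0, tr1 = int(rows[0]), int(rows[-1]) + 1
    tc0, tc1 = int(cols[0]), int(cols[-1]) + 1
    return InstanceMask(
        shape=(h, w),
        bbox=(cr0 + tr0, cr0 + tr1, cc0 + tc0, cc0 + tc1),
        crop=crop[tr0:tr1, tc0:tc1],
        score=inst.score,
        label_id=inst.label_id,
    )


def stitch_and_merge(
    per_tile: list[tuple[TileSpec, list[InstanceMask]]],
    source_shape: tuple[int, int],
    score_min: float = 0.7,
    overlap_max: float = 0.30,
    backend_name: str = "unknown",
) -> SegmentationResult:
    """Merge per-tile predictions into one result with the score-threshold
    and overlap-suppression rules.

    Instances with score <= ``score_min`` are dropped.  Tiles are visited
    in raster order (top-left to bottom-right) and, within a tile, by
    descending score (ties: ascending label_id); a candidate is kept iff
    its overlap with every already-kept mask is <= ``overlap_max`` of the
    candidate's own area (strictly more than the threshold discards).
    Duplicate detections in overlapping tiles are thereby suppressed, not
    fused.
    """
    h, w = int(source_shape[0]), int(source_shape[1])
    for spec, _ in per_tile:
        top, bottom, left, right = spec.pad
        if spec.origin[0] + spec.size > h + top + bottom or spec.origin[1] + spec.size > w + left + right:
            raise ParameterError(f"tile {spec} inconsistent with source shape {source_shape}")
    ordered = sorted(enumerate(per_tile), key=lambda kv: (kv[1][0].origin[0], kv[1][0].origin[1], kv[0]))
    kept: list[InstanceMask] = []
    n_dropped_score = 0
    n_dropped_overlap = 0
    for _, (spec, instances) in ordered:
        candidates = sorted(instances, key=lambda m: (-m.score, m.label_id))
        for cand in candidates:
            if cand.score <= score_min:
                n_dropped_score += 1
                continue
            mapped = _to_source_frame(cand, spec, (h, w))
            if mapped is None:
                continue
            area = mapped.area
            suppressed = False
            for prev in kept:
                if mapped.intersection_area(prev) / area > overlap_max:
                    suppressed = True
                    break
            if suppressed:
                n_dropped_overlap += 1
            else:
                kept.append(mapped)
    instances = [
        InstanceMask(shape=m.shape, bbox=m.bbox, crop=m.crop, score=m.score, label_id=i + 1)
        for i, m in enumerate(kept)
    ]
    return SegmentationResult(
        instances=instances,
        source_shape=(h, w),
        backend_name=backend_name,
        params={
            "score_min": score_min,
            "overlap_max": overlap_max,
            "n_dropped_score": n_dropped_score,
            "n_dropped_overlap": n_dropped_overlap,
        },
    )
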