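"""Image, mask and feature-table I/O plus contrast normalization.

All coordinates are 0-based, row-major, origin at the top-left corner, and
all geometry is in pixel units (the imaging data carries no micron
calibration).  Images are single-channel 2-D rasters: 8- or 16-bit PNG/TIFF
on disk, arbitrary non-negative (integer or real) arrays in memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError

REGIONS = ("anterior", "posterior", "unknown")
CONDITIONS = ("young", "aged", "cold_shock", "recovery", "control")


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition and biology metadata attached to one image.

    ``age_day`` is adult age in days (None when unknown); ``temperature_C``
    is the rearing or shock temperature in degrees Celsius.
    """

    animal_id: str = ""
    region: str = "unknown"
    condition: str = "control"
    age_day: int | None = None
    temperature_C: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ParameterError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class FluorescenceImage:
    """A 2-D non-negative intensity grid plus its metadata."""

    pixels: np.ndarray
    meta: ImageMeta = field(default_factory=ImageMeta)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError(f"pixels must be a non-empty 2-D array, got shape {self.pixels.shape}")
        if np.issubdtype(self.pixels.dtype, np.floating):
            if not np.all(np.isfinite(self.pixels)):
                raise FormatError("pixel intensities must be finite")
        if self.pixels.min() < 0:
            raise FormatError("pixel intensities must be non-negative")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


class InstanceMask:
    """One detected bead: a binary mask congruent with its source image.

    The mask is stored internally as a bounding box plus a cropped boolean
    array so that thousands of small instances on a large frame stay cheap;
    :attr:`mask` materializes the full-frame view on demand.

    ``score`` is the foreground probability in [0, 1] (1.0 for ground
    truth); ``label_id`` is a positive integer unique within one result.
    """

    __slots__ = ("shape", "score", "label_id", "bbox", "crop")

    def __init__(
        self,
        mask: np.ndarray | None = None,
        score: float = 1.0,
        label_id: int = 1,
        *,
        shape: tuple[int, int] | None = None,
        bbox: tuple[int, int, int, int] | None = None,
        crop: np.ndarray | None = None,
    ) -> None:
        if not (0.0 <= score <= 1.0):
            raise ParameterError(f"score must be in [0,1], got {score}")
        if label_id < 1:
            raise ParameterError(f"label_id must be a positive integer, got {label_id}")
        self.score = float(score)
        self.label_id = int(label_id)
        if mask is not None:
            mask = np.asarray(mask).astype(bool)
            if mask.ndim != 2:
                raise FormatError("mask must be 2-D")
            rows = np.flatnonzero(mask.any(axis=1))
            cols = np.flatnonzero(mask.any(axis=0))
            if rows.size == 0:
                raise FormatError("mask must have at least one foreground pixel")
            r0, r1 = int(rows[0]), int(rows[-1]) + 1
            c0, c1 = int(cols[0]), int(cols[-1]) + 1
            self.shape = (int(mask.shape[0]), int(mask.shape[1]))
            self.bbox = (r0, r1, c0, c1)
            self.crop = np.ascontiguousarray(mask[r0:r1, c0:c1])
        else:
            if shape is None or bbox is None or crop is None:
                raise ParameterError("either mask or (shape, bbox, crop) must be given")
            crop = np.asarray(crop).astype(bool)
            if not crop.any():
                raise FormatError("mask must have at least one foreground pixel")
            self.shape = (int(shape[0]), int(shape[1]))
            self.bbox = tuple(int(v) for v in bbox)  # type: ignore[assignment]
            self.crop = np.ascontiguousarray(crop)
            r0, r1, c0, c1 = self.bbox
            if not (0 <= r0 < r1 <= self.shape[0] and 0 <= c0 < c1 <= self.shape[1]):
                raise FormatError(f"bbox {self.bbox} outside frame {self.shape}")
            if crop.shape != (r1 - r0, c1 - c0):
                raise FormatError("crop shape inconsistent with bbox")

    @property
    def mask(self) -> np.ndarray:
        """Full-frame boolean mask (materialized copy)."""
        full = np.zeros(self.shape, dtype=bool)
        r0, r1, c0, c1 = self.bbox
        full[r0:r1, c0:c1] = self.crop
        return full

    @property
    def area(self) -> int:
        return int(self.crop.sum())

    def intersection_area(self, other: "InstanceMask") -> int:
        """Pixel count of the overlap with another instance (same frame)."""
        ar0, ar1, ac0, ac1 = self.bbox
        br0, br1, bc0, bc1 = other.bbox
        r0, r1 = max(ar0, br0), min(ar1, br1)
        c0, c1 = max(ac0, bc0), min(ac1, bc1)
        if r0 >= r1 or c0 >= c1:
            return 0
        a = self.crop[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
        b = other.crop[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
        return int(np.count_nonzero(a & b))

    def iou(self, other: "InstanceMask") -> float:
        inter = self.intersection_area(other)
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"InstanceMask(label={self.label_id}, score={self.score:.3f}, "
            f"area={self.area}, bbox={self.bbox})"
        )


@dataclass
class SegmentationResult:
    """An ordered set of instance masks for one image, with provenance."""

    instances: list[InstanceMask]
    source_shape: tuple[int, int]
    backend_name: str = "unknown"
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source_shape = (int(self.source_shape[0]), int(self.source_shape[1]))
        labels = [inst.label_id for inst in self.instances]
        if len(labels) != len(set(labels)):
            raise FormatError("label_ids must be unique within one result")
        for inst in self.instances:
            if inst.shape != self.source_shape:
                raise FormatError(
                    f"instance shape {inst.shape} != source shape {self.source_shape}"
                )

    def __len__(self) -> int:
        return len(self.instances)


# ---------------------------------------------------------------------------
# image I/O


def load_image(path: str | Path, meta: ImageMeta | None = None) -> FluorescenceImage:
    """Read a single-channel PNG/TIFF raster, preserving bit depth exactly.

    Multi-channel files are accepted only when all channels are identical
    (channel 0 is then taken); otherwise a :class:`FormatError` is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if all(np.array_equal(arr[..., 0], arr[..., k]) for k in range(1, arr.shape[-1])):
            arr = arr[..., 0]
        else:
            raise FormatError(f"{path}: multi-channel image with differing channels")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    return FluorescenceImage(arr, meta or ImageMeta())


def write_image(img: FluorescenceImage, path: str | Path) -> Path:
    """Write pixels to PNG/TIFF.  Float images are scaled to 16-bit."""
    path = Path(path)
    arr = img.pixels
    if np.issubdtype(arr.dtype, np.floating):
        hi = float(arr.max()) or 1.0
        arr = np.round(arr / hi * 65535.0).astype(np.uint16)
    iio.imwrite(path, arr)
    return path


# ---------------------------------------------------------------------------
# contrast normalization


def normalize_contrast(
    img: FluorescenceImage, low_frac: float = 0.01, high_frac: float = 0.01
) -> FluorescenceImage:
    """Linear contrast stretch with quantile saturation.

    The ``low_frac`` quantile maps to 0 and the ``1 - high_frac`` quantile to
    the full output range (dtype maximum for integer images, 1.0 for float),
    with clipping; the same tail-saturating stretch a practitioner gets from
    MATLAB's ``imadjust`` with default saturation.  A constant image is
    returned unchanged.
    """
    if not (0.0 <= low_frac and 0.0 <= high_frac and low_frac + high_frac < 1.0):
        raise ParameterError("require 0 <= low_frac + high_frac < 1")
    pix = img.pixels
    lo = float(np.quantile(pix, low_frac))
    hi = float(np.quantile(pix, 1.0 - high_frac))
    if hi <= lo:  # zero dynamic range between the two quantiles
        return FluorescenceImage(pix.copy(), img.meta)
    if np.issubdtype(pix.dtype, np.integer):
        max_out = float(np.iinfo(pix.dtype).max)
    else:
        max_out = 1.0
    stretched = (pix.astype(np.float64) - lo) / (hi - lo) * max_out
    stretched = np.clip(stretched, 0.0, max_out)
    if np.issubdtype(pix.dtype, np.integer):
        stretched = np.round(stretched).astype(pix.dtype)
    return FluorescenceImage(stretched, img.meta)


# ---------------------------------------------------------------------------
# mask serialization: labeled 16-bit image + JSON sidecar

_SIDE_SUFFIX = ".json"


def _rle_encode(mask: InstanceMask) -> list[int]:
    """Row-major run-length encoding [start, length, start, length, ...] of
    the full-frame mask, flattened."""
    h, w = mask.shape
    flat = np.zeros(h * w, dtype=bool)
    r0, r1, c0, c1 = mask.bbox
    for r in range(r0, r1):
        row = mask.crop[r - r0]
        flat[r * w + c0 : r * w + c1] = row
    padded = np.concatenate(([False], flat, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    out: list[int] = []
    for s, e in zip(starts, ends):
        out.extend((int(s), int(e - s)))
    return out


def _rle_decode(rle: Sequence[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    for s, n in zip(rle[::2], rle[1::2]):
        flat[s : s + n] = True
    return flat.reshape(shape)


def write_masks(result: SegmentationResult, path: str | Path) -> Path:
    """Serialize a result as a labeled 16-bit image plus a JSON sidecar.

    Pixels of instance *k* carry value *k* in the label image.  Instances
    whose pixels collide with an already-written label (merged/overlapping
    detections) are stored as run-length records in the sidecar instead, so
    the round trip is lossless.
    """
    path = Path(path)
    h, w = result.source_shape
    if any(inst.label_id > 65535 for inst in result.instances):
        raise FormatError("label_id exceeds 16-bit range")
    label_img = np.zeros((h, w), dtype=np.uint16)
    records = []
    for inst in result.instances:
        r0, r1, c0, c1 = inst.bbox
        window = label_img[r0:r1, c0:c1]
        if np.any(window[inst.crop] != 0):
            records.append(
                {
                    "label_id": inst.label_id,
                    "score": inst.score,
                    "encoding": "rle",
                    "rle": _rle_encode(inst),
                }
            )
        else:
            window[inst.crop] = inst.label_id
            records.append(
                {"label_id": inst.label_id, "score": inst.score, "encoding": "label"}
            )
    iio.imwrite(path, label_img)
    sidecar = {
        "shape": [h, w],
        "backend_name": result.backend_name,
        "params": result.params,
        "instances": records,
    }
    Path(str(path) + _SIDE_SUFFIX).write_text(
        json.dumps(sidecar, sort_keys=True, separators=(",", ":"))
    )
    return path


def read_masks(path: str | Path, source_shape: tuple[int, int] | None = None) -> SegmentationResult:
    """Inverse of :func:`write_masks`; validates shape when given."""
    path = Path(path)
    label_img = iio.imread(path)
    sidecar = json.loads(Path(str(path) + _SIDE_SUFFIX).read_text())
    shape = (int(sidecar["shape"][0]), int(sidecar["shape"][1]))
    if label_img.shape != shape:
        raise FormatError(f"label image shape {label_img.shape} != sidecar shape {shape}")
    if source_shape is not None and tuple(source_shape) != shape:
        raise FormatError(f"expected shape {tuple(source_shape)}, file has {shape}")
    instances = []
    for rec in sidecar["instances"]:
        if rec["encoding"] == "rle":
            mask = _rle_decode(rec["rle"], shape)
        else:
            mask = label_img == rec["label_id"]
        instances.append(InstanceMask(mask, score=rec["score"], label_id=rec["label_id"]))
    return SegmentationResult(
        instances=instances,
        source_shape=shape,
        backend_name=sidecar.get("backend_name", "unknown"),
        params=sidecar.get("params", {}),
    )


# ---------------------------------------------------------------------------
# feature tables and configs

METRIC_COLUMNS = [f"m{i:02d}" for i in range(1, 47)]


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with one row per image: m01..m46 first, metadata columns after."""
    path = Path(path)
    cols = [c for c in METRIC_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(cfg: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, sort_keys=True, indent=2))
    return path


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
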