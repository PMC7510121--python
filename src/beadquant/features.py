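"""Per-bead measurements and the canonical 46-metric phenotypic profile.

A segmented image is reduced to one :class:`BeadRecord` per instance
(geometry from the mask, intensities from the raw image) and then to a
46-slot :class:`FeatureVector46` summarizing bead counts, areas, spatial
dispersion (nearest-neighbor and all-pairwise centroid distances),
per-bead mean intensities, and shape.  Named anchor slots: m16 = fraction
of beads with area < 100 px, m17 = mean pairwise inter-bead distance,
m20 = SEM of pairwise distance, m21 = fraction of pairwise distances
< 150 px, m22 = fraction < 300 px, m25 = median area, m26 = max area,
m32 = median per-bead mean intensity, m35 = SD of per-bead mean
intensity, m37 = 90th percentile of bead intensity.  The remaining slots
fill out the same statistic families; "bead intensity" always means the
distribution over beads of each bead's mean intensity.

Conventions, pinned for cross-implementation determinism: percentiles use
linear interpolation between order statistics; standard deviations use
ddof=1 and are 0 when only one value exists; SEM = sd / sqrt(n); areas
in pixels; intensities raw (no background subtraction).  Metrics needing
at least one bead (area/intensity/shape families) or at least two beads
(distance families) are NaN-flagged undefined otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from skimage.measure import regionprops

from .core_io import METRIC_COLUMNS, FluorescenceImage, ImageMeta, SegmentationResult
from .errors import FormatError, ParameterError

#: Human-readable description of every metric slot, in order m01..m46.
METRIC_DESCRIPTIONS = {
    "m01": "bead count",
    "m02": "total bead area (px)",
    "m03": "mean bead area (px)",
    "m04": "SEM of bead area",
    "m05": "min bead area (px)",
    "m06": "fraction of beads with area in [0, 50)",
    "m07": "fraction of beads with area in [50, 100)",
    "m08": "fraction of beads with area in [100, 200)",
    "m09": "fraction of beads with area in [200, 400)",
    "m10": "fraction of beads with area >= 400",
    "m11": "mean nearest-neighbor distance (px)",
    "m12": "median nearest-neighbor distance (px)",
    "m13": "SD of nearest-neighbor distance",
    "m14": "min nearest-neighbor distance (px)",
    "m15": "max nearest-neighbor distance (px)",
    "m16": "fraction of beads with area < 100 px",
    "m17": "mean pairwise inter-bead distance (px)",
    "m18": "median pairwise inter-bead distance (px)",
    "m19": "SD of pairwise inter-bead distance",
    "m20": "SEM of pairwise inter-bead distance",
    "m21": "fraction of pairwise distances < 150 px",
    "m22": "fraction of pairwise distances < 300 px",
    "m23": "10th percentile of pairwise distance (px)",
    "m24": "90th percentile of pairwise distance (px)",
    "m25": "median bead area (px)",
    "m26": "max bead area (px)",
    "m27": "10th percentile of bead area (px)",
    "m28": "25th percentile of bead area (px)",
    "m29": "75th percentile of bead area (px)",
    "m30": "90th percentile of bead area (px)",
    "m31": "SD of bead area",
    "m32": "median bead intensity",
    "m33": "mean bead intensity",
    "m34": "SEM of bead intensity",
    "m35": "SD of mean bead intensity",
    "m36": "10th percentile of bead intensity",
    "m37": "90th percentile of bead intensity",
    "m38": "25th percentile of bead intensity",
    "m39": "75th percentile of bead intensity",
    "m40": "max bead intensity",
    "m41": "min bead intensity",
    "m42": "total integrated intensity",
    "m43": "mean eccentricity",
    "m44": "mean solidity",
    "m45": "CV of bead area",
    "m46": "CV of pairwise inter-bead distance",
}

SMALL_BEAD_AREA_PX = 100
CLOSE_PAIR_PX = 150
NEAR_PAIR_PX = 300


@dataclass(frozen=True)
class BeadRecord:
    """Derived measurements for one segmented bead."""

    label_id: int
    centroid: tuple[float, float]
    area_px: int
    mean_intensity: float
    median_intensity: float
    max_intensity: float
    min_intensity: float
    integrated_intensity: float
    eccentricity: float
    solidity: float


@dataclass
class FeatureVector46:
    """The canonical 46-slot profile of one image.

    ``values[i]`` is metric ``m{i+1:02d}``; undefined entries hold NaN and
    are flagged in ``undefined``.
    """

    values: np.ndarray
    undefined: np.ndarray
    meta: ImageMeta = field(default_factory=ImageMeta)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        if self.values.shape != (46,) or self.undefined.shape != (46,):
            raise FormatError("a feature vector has exactly 46 slots")

    def __getitem__(self, key: str) -> float:
        return float(self.values[METRIC_COLUMNS.index(key)])

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(METRIC_COLUMNS, self.values)}


def bead_records(img: FluorescenceImage, seg: SegmentationResult) -> list[BeadRecord]:
    """One record per instance: intensities measured on the raw image,
    shape measures from the mask geometry."""
    if img.shape != tuple(seg.source_shape):
        raise FormatError(f"image shape {img.shape} != segmentation shape {seg.source_shape}")
    records = []
    for inst in seg.instances:
        r0, r1, c0, c1 = inst.bbox
        crop = inst.crop
        if not crop.any():  # cannot normally happen; masks are non-empty
            warnings.warn(f"instance {inst.label_id} empty after clipping; skipped")
            continue
        img_crop = np.asarray(img.pixels[r0:r1, c0:c1], dtype=float)
        pixels = img_crop[crop]
        props = regionprops(crop.astype(np.uint8))[0]
        records.append(
            BeadRecord(
                label_id=inst.label_id,
                centroid=(r0 + float(props.centroid[0]), c0 + float(props.centroid[1])),
                area_px=int(crop.sum()),
                mean_intensity=float(pixels.mean()),
                median_intensity=float(np.median(pixels)),
                max_intensity=float(pixels.max()),
                min_intensity=float(pixels.min()),
                integrated_intensity=float(pixels.sum()),
                eccentricity=float(props.eccentricity),
                solidity=float(props.solidity),
            )
        )
    return records


def pairwise_distances(records: list[BeadRecord]) -> list[float]:
    """Euclidean centroid distances over all C(n,2) unordered pairs."""
    if len(records) < 2:
        return []
    pts = np.array([r.centroid for r in records])
    return [float(d) for d in pdist(pts)]


def _nearest_neighbor_distances(records: list[BeadRecord]) -> np.ndarray:
    pts = np.array([r.centroid for r in records])
    from scipy.spatial.distance import squareform

    dm = squareform(pdist(pts))
    np.fill_diagonal(dm, np.inf)
    return dm.min(axis=1)


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def _sem(x: np.ndarray) -> float:
    return _sd(x) / math.sqrt(x.size)


def feature_vector(
    records: list[BeadRecord],
    distances: list[float] | None = None,
    img_meta: ImageMeta | None = None,
) -> FeatureVector46:
    """Fill the canonical 46-metric table from per-bead records."""
    if distances is None:
        distances = pairwise_distances(records)
    n = len(records)
    v = np.full(46, np.nan)
    undef = np.ones(46, dtype=bool)

    def put(name: str, value: float) -> None:
        idx = METRIC_COLUMNS.index(name)
        v[idx] = value
        undef[idx] = False

    put("m01", float(n))
    put("m02", float(sum(r.area_px for r in records)))
    if n >= 1:
        areas = np.array([r.area_px for r in records], dtype=float)
        mu = np.array([r.mean_intensity for r in records])
        put("m03", float(areas.mean()))
        put("m04", _sem(areas))
        put("m05", float(areas.min()))
        edges = [0, 50, 100, 200, 400, np.inf]
        for k, name in enumerate(["m06", "m07", "m08", "m09", "m10"]):
            put(name, float(np.mean((areas >= edges[k]) & (areas < edges[k + 1]))))
        put("m16", float(np.mean(areas < SMALL_BEAD_AREA_PX)))
        put("m25", float(np.median(areas)))
        put("m26", float(areas.max()))
        put("m27", float(np.percentile(areas, 10)))
        put("m28", float(np.percentile(areas, 25)))
        put("m29", float(np.percentile(areas, 75)))
        put("m30", float(np.percentile(areas, 90)))
        put("m31", _sd(areas))
        put("m32", float(np.median(mu)))
        put("m33", float(mu.mean()))
        put("m34", _sem(mu))
        put("m35", _sd(mu))
        put("m36", float(np.percentile(mu, 10)))
        put("m37", float(np.percentile(mu, 90)))
        put("m38", float(np.percentile(mu, 25)))
        put("m39", float(np.percentile(mu, 75)))
        put("m40", float(mu.max()))
        put("m41", float(mu.min()))
        put("m42", float(sum(r.integrated_intensity for r in records)))
        put("m43", float(np.mean([r.eccentricity for r in records])))
        put("m44", float(np.mean([r.solidity for r in records])))
        if areas.mean() > 0:
            put("m45", _sd(areas) / float(areas.mean()))
    if n >= 2:
        nn = _nearest_neighbor_distances(records)
        put("m11", float(nn.mean()))
        put("m12", float(np.median(nn)))
        put("m13", _sd(nn))
        put("m14", float(nn.min()))
        put("m15", float(nn.max()))
        d = np.asarray(distances, dtype=float)
        put("m17", float(d.mean()))
        put("m18", float(np.median(d)))
        put("m19", _sd(d))
        put("m20", _sem(d))
        put("m21", float(np.mean(d < CLOSE_PAIR_PX)))
        put("m22", float(np.mean(d < NEAR_PAIR_PX)))
        put("m23", float(np.percentile(d, 10)))
        put("m24", float(np.percentile(d, 90)))
        if d.mean() > 0:
            put("m46", _sd(d) / float(d.mean()))
    return FeatureVector46(values=v, undefined=undef, meta=img_meta or ImageMeta())


def profile_image(img: FluorescenceImage, seg: SegmentationResult) -> FeatureVector46:
    """Convenience: records -> distances -> 46-metric vector."""
    records = bead_records(img, seg)
    return feature_vector(records, img_meta=img.meta)


def feature_table(vectors: list[FeatureVector46]) -> pd.DataFrame:
    """One row per image: m01..m46 plus metadata columns."""
    rows = []
    for vec in vectors:
        row = vec.as_dict()
        row.update(
            animal_id=vec.meta.animal_id,
            region=vec.meta.region,
            condition=vec.meta.condition,
            age_day=vec.meta.age_day,
            temperature_C=vec.meta.temperature_C,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def population_summary(
    table: pd.DataFrame, group_cols: tuple[str, ...] = ("condition", "region")
) -> pd.DataFrame:
    """Per-group per-metric mean, SEM (sd/sqrt(n), ddof=1) and n,
    ignoring NaN-flagged (undefined) entries."""
    metrics = [c for c in METRIC_COLUMNS if c in table.columns]
    if not metrics:
        raise ParameterError("table contains no metric columns m01..m46")
    out_rows = []
    for keys, group in table.groupby(list(group_cols), dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for m in metrics:
            vals = group[m].dropna().to_numpy(dtype=float)
            out_rows.append(
                dict(
                    zip(group_cols, keys),
                    metric=m,
                    mean=float(vals.mean()) if vals.size else float("nan"),
                    sem=_sem(vals) if vals.size else float("nan"),
                    n=int(vals.size),
                )
            )
    return pd.DataFrame(out_rows)


def bonferroni_alpha(family_alpha: float = 0.05, n_comparisons: int = 1) -> tuple[float, float]:
    """Bonferroni-corrected per-comparison significance level.

    Returns (display, exact): the exact value ``family_alpha / n`` and a
    display value truncated (floored) to 3 decimal places, matching the
    printed convention alpha = 0.016 for 0.05 over 3 comparisons.
    """
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")
    exact = family_alpha / n_comparisons
    display = math.floor(exact * 1000) / 1000
    return display, exact
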