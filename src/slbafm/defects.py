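"""Defect segmentation, depth statistics and Table-style aggregation.

Defects are the 8-connected components of the uncovered phase of a binarised
topograph.  Each defect's depth — an estimate of the bilayer thickness — is
the local lipid background (median height of an annular ring of covered
pixels around the defect) minus a floor statistic of the defect interior.
Depths above an outlier cutoff (default 7 nm) are discarded as multilayer
pits, or alternatively the depth list is split into thin/thick populations
at 6 nm when a condition shows two defect classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, map_coordinates
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

from .coverage import CoverageResult
from .raster_io import HeightMap, Manifest

__all__ = [
    "DefectRecord",
    "DepthPopulations",
    "SampleSummary",
    "label_defects",
    "defect_depth",
    "measure_defects",
    "classify_depths",
    "rms_roughness",
    "height_profile",
    "aggregate",
    "summaries_to_frame",
]

DEFAULT_OUTLIER_CUTOFF = 7.0  # nm; depths above are discounted as multilayer pits
DEFAULT_SPLIT = 6.0  # nm; thin/thick population boundary


@dataclass
class DefectRecord:
    """One segmented uncovered region."""

    label: int
    area: float  # nm²
    equivalent_diameter: float  # nm, diameter of the circle of equal area
    centroid: tuple[float, float]  # (row, col), pixels
    touches_border: bool
    depth: float | None = None  # nm, filled by defect_depth
    coords: np.ndarray = field(default=None, repr=False)  # (n, 2) pixel indices


@dataclass
class DepthPopulations:
    """Outcome of the outlier / population-split rules on a depth list."""

    thin: list[float]
    thick: list[float]
    split: float
    outlier_cutoff: float
    n_discarded: int

    @staticmethod
    def _mean_sd(values: list[float]) -> tuple[float, float | None]:
        if not values:
            return math.nan, None
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
        return mean, sd

    @property
    def thin_mean_sd(self) -> tuple[float, float | None]:
        return self._mean_sd(self.thin)

    @property
    def thick_mean_sd(self) -> tuple[float, float | None]:
        return self._mean_sd(self.thick)


@dataclass
class SampleSummary:
    """One aggregate row: mean ± SD coverage and depth populations."""

    condition: str
    sample_ids: tuple[str, ...]
    n_images: int
    mean_coverage: float
    sd_coverage: float | None  # None when n_images == 1
    depths: DepthPopulations | None


def label_defects(
    mask: np.ndarray,
    pixel_size: float,
    min_area: float | None = None,
) -> list[DefectRecord]:
    """Segment uncovered (False) regions under 8-connectivity.

    ``min_area`` is in nm² and defaults to 4 pixels' worth; smaller components
    are treated as threshold noise and dropped.  Border-touching components
    are retained but flagged (they contribute to coverage, not to depth
    statistics).
    """
    mask = np.asarray(mask, bool)
    px_area = pixel_size**2
    if min_area is None:
        min_area = 4 * px_area
    labels = cc_label(~mask, connectivity=2)
    rows, cols = mask.shape
    records = []
    for prop in regionprops(labels):
        area_nm2 = prop.area * px_area
        if area_nm2 < min_area:
            continue
        minr, minc, maxr, maxc = prop.bbox
        records.append(
            DefectRecord(
                label=int(prop.label),
                area=float(area_nm2),
                equivalent_diameter=float(2.0 * np.sqrt(area_nm2 / np.pi)),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                touches_border=bool(
                    minr == 0 or minc == 0 or maxr == rows or maxc == cols
                ),
                coords=prop.coords,
            )
        )
    return records


def defect_depth(
    hmap: HeightMap,
    defect: DefectRecord,
    ring_width: int = 3,
    covered_mask: np.ndarray | None = None,
    floor_stat: str = "median",
) -> float:
    """Background-subtracted depth of one defect (nm).

    Depth = median height of the annular ring of covered pixels within
    ``ring_width`` pixels of the defect boundary, minus a floor statistic of
    the defect interior: ``"median"`` (default, unbiased under symmetric
    roughness) or ``"p10"`` (10th percentile, a spike-resistant proxy for the
    deepest credible floor).  Never negative (clamped at 0).
    """
    if ring_width < 2:
        raise ValueError("ring_width must be >= 2")
    if defect.touches_border:
        raise ValueError(f"defect {defect.label}: no complete background ring (touches border)")
    if floor_stat not in ("median", "p10"):
        raise ValueError("floor_stat must be 'median' or 'p10'")
    h = hmap.heights
    region = np.zeros(h.shape, dtype=bool)
    region[defect.coords[:, 0], defect.coords[:, 1]] = True
    ring = binary_dilation(region, structure=disk(ring_width)) & ~region
    if covered_mask is not None:
        ring &= np.asarray(covered_mask, bool)
    if ring.sum() < 10:
        raise ValueError(f"defect {defect.label}: ring contains fewer than 10 covered pixels")
    background = float(np.median(h[ring]))
    interior = h[region]
    floor = float(np.median(interior)) if floor_stat == "median" else float(
        np.percentile(interior, 10)
    )
    return max(background - floor, 0.0)


def measure_defects(
    hmap: HeightMap,
    result: CoverageResult,
    ring_width: int = 3,
    min_area: float | None = None,
    floor_stat: str = "median",
) -> list[DefectRecord]:
    """Label all defects of a coverage result and fill in measurable depths.

    Border-touching defects and defects without a valid background ring keep
    ``depth=None``.  Uses the flattened map stored on the result when present.
    """
    source = result.flattened or hmap
    records = label_defects(result.mask, source.pixel_size, min_area=min_area)
    for rec in records:
        if rec.touches_border:
            continue
        try:
            rec.depth = defect_depth(
                source, rec, ring_width=ring_width, covered_mask=result.mask,
                floor_stat=floor_stat,
            )
        except ValueError:
            rec.depth = None
    return records


def classify_depths(
    depths: list[float],
    outlier_cutoff: float = DEFAULT_OUTLIER_CUTOFF,
    split: float = DEFAULT_SPLIT,
    population_mode: bool = False,
) -> DepthPopulations:
    """Apply the outlier rule or the two-population split to a depth list.

    With ``population_mode`` off, values above ``outlier_cutoff`` are
    discounted as outliers (multilayer pits) and the remainder forms the thin
    population.  With it on, nothing is discarded: the list is partitioned at
    ``split`` into thin (≤ split) and thick (> split) populations.  The two
    rules are mutually exclusive.
    """
    depths = [float(d) for d in depths]
    if not depths:
        raise ValueError("depths is empty")
    if population_mode:
        thin = [d for d in depths if d <= split]
        thick = [d for d in depths if d > split]
        n_discarded = 0
    else:
        thin = [d for d in depths if d <= outlier_cutoff]
        thick = []
        n_discarded = len(depths) - len(thin)
        if not thin:
            raise ValueError("no retained depths (all values above the outlier cutoff)")
    return DepthPopulations(
        thin=thin, thick=thick, split=split, outlier_cutoff=outlier_cutoff,
        n_discarded=n_discarded,
    )


def rms_roughness(hmap: HeightMap, mask: np.ndarray | None = None) -> float:
    """RMS deviation of heights about the region mean (nm).

    ``mask`` selects the region (True = include); default is the whole map.
    """
    h = hmap.heights
    values = h[np.asarray(mask, bool)] if mask is not None else h.ravel()
    if values.size < 16:
        raise ValueError(f"region has only {values.size} pixels (need >= 16)")
    return float(np.sqrt(np.mean((values - values.mean()) ** 2)))


def height_profile(
    hmap: HeightMap,
    start: tuple[float, float],
    end: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinearly interpolated height profile along a segment.

    ``start`` and ``end`` are (row, col) pixel coordinates; returns
    ``(distance nm, height nm)`` sampled at most one pixel apart.
    """
    rows, cols = hmap.shape
    for point in (start, end):
        if not (0 <= point[0] <= rows - 1 and 0 <= point[1] <= cols - 1):
            raise ValueError(f"endpoint {point} outside grid {hmap.shape}")
    length_px = math.hypot(end[0] - start[0], end[1] - start[1])
    if length_px == 0:
        raise ValueError("zero-length segment")
    n = int(np.ceil(length_px)) + 1
    r = np.linspace(start[0], end[0], n)
    c = np.linspace(start[1], end[1], n)
    heights = map_coordinates(hmap.heights, [r, c], order=1, mode="nearest")
    distance = np.linspace(0.0, length_px * hmap.pixel_size, n)
    return distance, heights


def aggregate(
    images: dict[str, tuple[CoverageResult, list[float]]],
    manifest: Manifest,
    outlier_cutoff: float = DEFAULT_OUTLIER_CUTOFF,
    split: float = DEFAULT_SPLIT,
    population_mode: bool | dict[str, bool] = False,
) -> list[SampleSummary]:
    """Aggregate per-image results to one summary row per condition.

    ``images`` maps image path (string) to ``(CoverageResult, depth list)``.
    Per condition: mean and sample SD (n−1 denominator) of the per-image
    coverages; the pooled depth list is re-classified with
    :func:`classify_depths`.  ``population_mode`` may be a single flag or a
    per-condition mapping.  Warns (never errors) when a condition has fewer
    than 10 images or fewer than 2 samples; rows follow manifest order.
    """
    summaries = []
    for condition in manifest.conditions:
        entries = [e for e in manifest.entries if e.condition == condition]
        if not entries:
            raise ValueError(f"condition {condition!r} has zero images")
        coverages, depths, samples = [], [], []
        for e in entries:
            key = str(e.path)
            if key not in images:
                raise KeyError(f"no analysis result for manifest entry {key}")
            result, image_depths = images[key]
            coverages.append(result.coverage_percent)
            depths.extend(image_depths)
            if e.sample_id not in samples:
                samples.append(e.sample_id)
        if len(entries) < 10:
            warnings.warn(
                f"condition {condition!r}: only {len(entries)} images (protocol asks >= 10)",
                stacklevel=2,
            )
        if len(samples) < 2:
            warnings.warn(
                f"condition {condition!r}: only {len(samples)} sample(s) (protocol asks >= 2)",
                stacklevel=2,
            )
        pop_mode = (
            population_mode.get(condition, False)
            if isinstance(population_mode, dict)
            else population_mode
        )
        summaries.append(
            SampleSummary(
                condition=condition,
                sample_ids=tuple(samples),
                n_images=len(entries),
                mean_coverage=float(np.mean(coverages)),
                sd_coverage=(
                    float(np.std(coverages, ddof=1)) if len(coverages) > 1 else None
                ),
                depths=(
                    classify_depths(
                        depths, outlier_cutoff=outlier_cutoff, split=split,
                        population_mode=pop_mode,
                    )
                    if depths
                    else None
                ),
            )
        )
    return summaries


def summaries_to_frame(summaries: list[SampleSummary]):
    """Summaries as a tidy table mirroring the deposition-survey layout."""
    import pandas as pd

    rows = []
    for s in summaries:
        thin_mean, thin_sd = s.depths.thin_mean_sd if s.depths else (math.nan, None)
        thick_mean, thick_sd = s.depths.thick_mean_sd if s.depths else (math.nan, None)
        rows.append(
            {
                "condition": s.condition,
                "n_samples": len(s.sample_ids),
                "n_images": s.n_images,
                "coverage_mean_pct": round(s.mean_coverage, 1),
                "coverage_sd_pct": round(s.sd_coverage, 1) if s.sd_coverage is not None else "NA",
                "depth_thin_mean_nm": round(thin_mean, 2) if not math.isnan(thin_mean) else "NA",
                "depth_thin_sd_nm": round(thin_sd, 2) if thin_sd is not None else "NA",
                "depth_thick_mean_nm": (
                    round(thick_mean, 2) if s.depths and s.depths.thick else "NA"
                ),
                "depth_thick_sd_nm": round(thick_sd, 2) if thick_sd is not None else "NA",
                "n_depths_discarded": s.depths.n_discarded if s.depths else 0,
            }
        )
    return pd.DataFrame(rows)
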