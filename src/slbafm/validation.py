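"""Ground-truth recovery benchmarks on seeded synthetic scenes.

These routines generate scenes under the study conditions (512×512 px at
10 nm/px, roughness σ 0.3 nm, tilt 0.05 nm/px, line offsets σ 0.5 nm), run
the full pipeline on them, and compare the measurements with the generator's
exact ground truth.  They back both the validation test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .coverage import analyze_image
from .defects import label_defects, measure_defects
from .preprocess import FlattenConfig
from .synthetic import SyntheticScene, generate_scene

__all__ = [
    "coverage_scene",
    "coverage_recovery",
    "depth_scene",
    "depth_recovery",
    "geometry_recovery",
]

#: per-level scene parameters used for coverage recovery (coverage fraction →
#: defect diameter mean/sd in nm, overlap flag); diameters shrink with rising
#: coverage the way the deposition survey's defect sizes do, and the
#: half-covered level uses merged (overlapping) uncovered regions — disjoint
#: circles jam well before half the area is uncovered, and real half-covered
#: surfaces are coalescing island morphologies
COVERAGE_LEVELS: dict[float, tuple[float, float, bool]] = {
    0.50: (500.0, 200.0, True),
    0.72: (1000.0, 300.0, False),
    0.85: (200.0, 60.0, False),
    0.97: (200.0, 60.0, False),
    0.99: (150.0, 40.0, False),
}


def coverage_scene(level: float, seed: int, grid: tuple[int, int] = (512, 512)) -> SyntheticScene:
    diam_mean, diam_sd, overlap = COVERAGE_LEVELS[level]
    return SyntheticScene(
        grid=grid,
        target_coverage=level,
        defect_diameter_mean=diam_mean,
        defect_diameter_sd=diam_sd,
        allow_overlap=overlap,
        seed=seed,
    )


def coverage_recovery(
    seeds: list[int],
    levels: tuple[float, ...] = (0.50, 0.72, 0.85, 0.97, 0.99),
    grid: tuple[int, int] = (512, 512),
) -> dict[float, dict]:
    """Run the full pipeline per level × seed; absolute coverage errors.

    Returns per level: achieved true coverages (%), measured coverages (%),
    and the mean absolute error (percentage points).
    """
    out: dict[float, dict] = {}
    for level in levels:
        truths, measured = [], []
        for seed in seeds:
            hmap, truth = generate_scene(coverage_scene(level, seed, grid))
            result = analyze_image(hmap, FlattenConfig())
            truths.append(100.0 * truth.true_coverage)
            measured.append(result.coverage_percent)
        errors = np.abs(np.array(measured) - np.array(truths))
        out[level] = {
            "true_pct": truths,
            "measured_pct": measured,
            "mae_pp": float(errors.mean()),
        }
    return out


def depth_scene(depth: float, seed: int, grid: tuple[int, int] = (256, 256)) -> SyntheticScene:
    return SyntheticScene(
        grid=grid,
        target_coverage=0.75,
        defect_diameter_mean=300.0,
        defect_diameter_sd=60.0,
        defect_depth=depth,
        seed=seed,
    )


def depth_recovery(
    depth: float, seeds: list[int], grid: tuple[int, int] = (256, 256)
) -> dict:
    """Measured defect depths pooled over seeds for one construction depth."""
    depths: list[float] = []
    for seed in seeds:
        hmap, truth = generate_scene(depth_scene(depth, seed, grid))
        result = analyze_image(hmap, FlattenConfig())
        records = measure_defects(hmap, result)
        depths.extend(r.depth for r in records if r.depth is not None)
    arr = np.array(depths)
    return {
        "true_depth": depth,
        "depths": depths,
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "abs_error": float(abs(arr.mean() - depth)),
    }


def geometry_recovery(
    diameter: float, seed: int, target_coverage: float = 0.88,
    grid: tuple[int, int] = (512, 512),
) -> dict:
    """Recover circular-defect diameters on one seeded scene.

    Ground-truth defects are matched to labelled components by centroid; the
    per-defect diameter error is reported in nm and in pixel equivalents.
    """
    spec = SyntheticScene(
        grid=grid,
        target_coverage=target_coverage,
        defect_diameter_mean=diameter,
        defect_diameter_sd=0.15 * diameter,
        seed=seed,
    )
    hmap, truth = generate_scene(spec)
    result = analyze_image(hmap, FlattenConfig())
    records = label_defects(result.mask, hmap.pixel_size)
    centroids = np.array([r.centroid for r in records])
    true_d, found_d = [], []
    for defect in truth.defect_list:
        d2 = np.sum((centroids - np.array(defect["center"])) ** 2, axis=1)
        nearest = int(np.argmin(d2))
        radius_px = defect["diameter"] / 2.0 / hmap.pixel_size
        if d2[nearest] > radius_px**2:  # no matching component
            continue
        true_d.append(defect["diameter"])
        found_d.append(records[nearest].equivalent_diameter)
    true_arr, found_arr = np.array(true_d), np.array(found_d)
    err_nm = np.abs(found_arr - true_arr)
    return {
        "n": int(true_arr.size),
        "n_generated": len(truth.defect_list),
        "true_mean_nm": float(true_arr.mean()),
        "measured_mean_nm": float(found_arr.mean()),
        "mean_abs_error_nm": float(err_nm.mean()),
        "mean_abs_error_px": float(err_nm.mean() / hmap.pixel_size),
    }
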