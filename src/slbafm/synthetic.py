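"""Seeded synthetic AFM topographs of supported lipid bilayers.

Generates height maps that emulate flattened bilayer deposition images: a
substrate plane, a lipid terrace one bilayer thickness (~4.5 nm) above it
covering a target fraction of the surface, roughly circular defects
(diameters ~0.2–1 μm) punched through the terrace, optional multilayer
islands (8–15 nm total height), optional partially fused vesicle caps
(tens of nm tall, lateral size below the ~100–150 nm vesicle diameter), and
instrument artifacts: plane tilt, per-scan-line offsets and Gaussian
roughness.  The generator records exact ground truth (covered mask, achieved
coverage, per-defect centre/diameter/depth) *before* artifacts are applied,
so every analysis stage can be validated against construction.

Coverage is controlled by punching non-overlapping circles until the covered
fraction lies within ±0.5 percentage points of the target; the ground truth
records the exact achieved fraction, never the requested one.

Determinism: a scene is a pure function of its spec (including ``seed``).
Independent random sub-streams are used per construction stage, so e.g.
switching noise off does not move the defects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count

import numpy as np

from .raster_io import HeightMap

__all__ = ["SyntheticScene", "GroundTruth", "generate_scene", "scene_presets", "PRESETS"]

MAX_ATTEMPTS = 10_000  # rejection-sampling budget for defect placement
COVERAGE_TOL = 0.005  # achieved-coverage band half-width (fraction)


@dataclass
class SyntheticScene:
    """Parameters of one synthetic topograph.

    Lengths are nm; the defaults are the study conditions used throughout the
    validation suite (512×512 px at 10 nm/px — a 5.12 μm scan; bilayer
    4.5 nm; roughness σ 0.3 nm; tilt 0.05 nm/px; line offsets σ 0.5 nm).
    """

    grid: tuple[int, int] = (512, 512)
    pixel_size: float = 10.0
    bilayer_thickness: float = 4.5
    target_coverage: float = 0.72
    defect_diameter_mean: float = 1000.0
    defect_diameter_sd: float = 300.0
    defect_depth: float | None = None  # None → bilayer_thickness (floor = substrate)
    deep_defect_fraction: float = 0.0  # fraction of defects punched as multilayer pits
    deep_defect_depth: float = 8.5
    multilayer_fraction: float = 0.0  # fraction of covered area carrying +1 bilayer
    multilayer_island_diameter: float = 500.0
    vesicle_cap_count: int = 0
    cap_diameter: float = 120.0  # ≤ vesicle Z-average (100–150 nm)
    noise_sd: float = 0.3
    tilt: tuple[float, float] = (0.05, 0.05)  # nm/px along (row, col)
    line_offset_sd: float = 0.5
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_coverage <= 1.0:
            raise ValueError("target_coverage must be in [0, 1]")
        for name in ("defect_diameter_sd", "noise_sd", "line_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.deep_defect_fraction <= 1.0:
            raise ValueError("deep_defect_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact construction record captured before instrument artifacts."""

    covered_mask: np.ndarray
    true_coverage: float  # exact covered fraction of covered_mask
    defect_list: list[dict] = field(default_factory=list)  # center px, diameter nm, depth nm
    feature_list: list[dict] = field(default_factory=list)  # multilayer / vesicle features


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _disk_indices(
    center: tuple[float, float], radius_px: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    r0, c0 = center
    rmin = max(int(np.floor(r0 - radius_px)), 0)
    rmax = min(int(np.ceil(r0 + radius_px)) + 1, shape[0])
    cmin = max(int(np.floor(c0 - radius_px)), 0)
    cmax = min(int(np.ceil(c0 + radius_px)) + 1, shape[1])
    rr, cc = np.mgrid[rmin:rmax, cmin:cmax]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    return rr[inside], cc[inside]


def _punch_defects(
    heights: np.ndarray,
    covered: np.ndarray,
    spec: SyntheticScene,
    rng: np.random.Generator,
) -> list[dict]:
    """Punch circular defects until covered fraction is within the band."""
    shape = heights.shape
    total = heights.size
    mu, sigma = _lognormal_params(spec.defect_diameter_mean, spec.defect_diameter_sd)
    placed: list[tuple[float, float, float]] = []  # (r, c, radius_px)
    records: list[dict] = []
    gap_px = 3.0  # keeps background rings of neighbouring defects disjoint
    target = spec.target_coverage
    current = covered.sum() / total
    attempts = 0
    while current > target + COVERAGE_TOL:
        attempts += 1
        if attempts > MAX_ATTEMPTS:
            raise RuntimeError(
                f"could not reach coverage {target:.3f} within {MAX_ATTEMPTS} attempts "
                f"(achieved {current:.3f}); diameter distribution too coarse for the grid"
            )
        diameter = float(np.exp(rng.normal(mu, sigma))) if sigma > 0 else float(np.exp(mu))
        radius_px = diameter / 2.0 / spec.pixel_size
        if radius_px < 1.0:
            continue
        margin = radius_px + 2.0
        if shape[0] - 1 - margin <= margin or shape[1] - 1 - margin <= margin:
            continue
        r0 = rng.uniform(margin, shape[0] - 1 - margin)
        c0 = rng.uniform(margin, shape[1] - 1 - margin)
        if not spec.allow_overlap and placed:
            arr = np.array([(p[0], p[1], p[2]) for p in placed])
            d2 = (arr[:, 0] - r0) ** 2 + (arr[:, 1] - c0) ** 2
            if np.any(d2 <= (arr[:, 2] + radius_px + gap_px) ** 2):
                continue
        rr, cc = _disk_indices((r0, c0), radius_px, shape)
        newly = covered[rr, cc].sum() if spec.allow_overlap else rr.size
        after = current - newly / total
        if after < target - COVERAGE_TOL:
            continue  # this circle would overshoot the band
        depth = spec.defect_depth if spec.defect_depth is not None else spec.bilayer_thickness
        if spec.deep_defect_fraction > 0 and rng.random() < spec.deep_defect_fraction:
            depth = spec.deep_defect_depth
        heights[rr, cc] = spec.bilayer_thickness - depth
        covered[rr, cc] = False
        placed.append((r0, c0, radius_px))
        records.append(
            {"center": (r0, c0), "diameter": diameter, "depth": float(depth)}
        )
        current = after if not spec.allow_overlap else covered.sum() / total
    return records


def _add_multilayers(
    heights: np.ndarray,
    covered: np.ndarray,
    spec: SyntheticScene,
    rng: np.random.Generator,
) -> list[dict]:
    features: list[dict] = []
    covered_px = int(covered.sum())
    if covered_px == 0 or spec.multilayer_fraction <= 0:
        return features
    target_px = spec.multilayer_fraction * covered_px
    raised = np.zeros_like(covered)
    mu, sigma = _lognormal_params(spec.multilayer_island_diameter, 0.3 * spec.multilayer_island_diameter)
    cov_idx = np.flatnonzero(covered.ravel())
    for _ in range(1000):
        if raised.sum() >= target_px:
            break
        flat = int(rng.choice(cov_idx))
        r0, c0 = divmod(flat, heights.shape[1])
        diameter = float(np.exp(rng.normal(mu, sigma)))
        total_height = float(rng.uniform(8.0, 15.0))  # stacked-bilayer step heights
        rr, cc = _disk_indices((r0, c0), diameter / 2.0 / spec.pixel_size, heights.shape)
        sel = covered[rr, cc] & ~raised[rr, cc]
        heights[rr[sel], cc[sel]] += total_height - spec.bilayer_thickness
        raised[rr[sel], cc[sel]] = True
        features.append(
            {"kind": "multilayer", "center": (float(r0), float(c0)),
             "diameter": diameter, "total_height": total_height}
        )
    return features


def _add_vesicle_caps(
    heights: np.ndarray,
    covered: np.ndarray,
    spec: SyntheticScene,
    rng: np.random.Generator,
) -> list[dict]:
    features: list[dict] = []
    if spec.vesicle_cap_count <= 0:
        return features
    cov_idx = np.flatnonzero(covered.ravel())
    if cov_idx.size == 0:
        return features
    for _ in range(spec.vesicle_cap_count):
        flat = int(rng.choice(cov_idx))
        r0, c0 = divmod(flat, heights.shape[1])
        diameter = float(rng.uniform(0.6, 1.0) * spec.cap_diameter)
        a = diameter / 2.0  # base radius, nm
        # spherical cap: much taller than a bilayer, lower than the vesicle diameter
        h_cap = float(rng.uniform(max(10.0, 0.15 * diameter), 0.45 * diameter))
        sphere_r = (a**2 + h_cap**2) / (2.0 * h_cap)
        rr, cc = _disk_indices((r0, c0), a / spec.pixel_size, heights.shape)
        dist_nm = np.hypot((rr - r0), (cc - c0)) * spec.pixel_size
        cap = np.sqrt(np.maximum(sphere_r**2 - dist_nm**2, 0.0)) - (sphere_r - h_cap)
        heights[rr, cc] += np.maximum(cap, 0.0)
        features.append(
            {"kind": "vesicle_cap", "center": (float(r0), float(c0)),
             "diameter": diameter, "cap_height": h_cap}
        )
    return features


def generate_scene(spec: SyntheticScene) -> tuple[HeightMap, GroundTruth]:
    """Build one scene: terrace → defects → features → artifacts.

    Ground truth (covered mask, exact achieved coverage, defect geometry) is
    captured before tilt, line offsets and pixel noise are applied.
    """
    rows, cols = spec.grid
    ss = np.random.SeedSequence(spec.seed)
    rng_defects, rng_features, rng_lines, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    if spec.target_coverage == 0.0:
        heights = np.zeros((rows, cols))
        covered = np.zeros((rows, cols), dtype=bool)
        defect_records: list[dict] = []
    else:
        heights = np.full((rows, cols), spec.bilayer_thickness, dtype=float)
        covered = np.ones((rows, cols), dtype=bool)
        defect_records = (
            _punch_defects(heights, covered, spec, rng_defects)
            if spec.target_coverage < 1.0
            else []
        )

    features = _add_multilayers(heights, covered, spec, rng_features)
    features += _add_vesicle_caps(heights, covered, spec, rng_features)

    truth = GroundTruth(
        covered_mask=covered.copy(),
        true_coverage=float(covered.sum() / covered.size),
        defect_list=defect_records,
        feature_list=features,
    )

    # instrument artifacts (after ground-truth capture)
    r_idx = np.arange(rows)[:, None]
    c_idx = np.arange(cols)[None, :]
    heights = heights + spec.tilt[0] * r_idx + spec.tilt[1] * c_idx
    if spec.line_offset_sd > 0:
        heights = heights + rng_lines.normal(0.0, spec.line_offset_sd, size=rows)[:, None]
    if spec.noise_sd > 0:
        heights = heights + rng_noise.normal(0.0, spec.noise_sd, size=(rows, cols))

    hmap = HeightMap(
        heights=heights,
        pixel_size=spec.pixel_size,
        name=f"synthetic-seed{spec.seed}",
        provenance=(
            f"synthetic scene: target_coverage={spec.target_coverage}, "
            f"bilayer={spec.bilayer_thickness} nm, noise_sd={spec.noise_sd} nm, "
            f"tilt={spec.tilt} nm/px, seed={spec.seed}"
        ),
    )
    return hmap, truth


#: named deposition conditions (coverage / depth pairs from the deposition survey)
PRESETS: dict[str, dict] = {
    # LB/LS DMPC on UPW, 16 °C: 72% coverage, ~1 μm defects, 4.5 nm deep
    "lbls_upw": dict(target_coverage=0.72, bilayer_thickness=4.5,
                     defect_diameter_mean=1000.0, defect_diameter_sd=300.0),
    # LB/LS DMPC on CaCl2: better coverage, ~0.2 μm defects
    "lbls_ca": dict(target_coverage=0.85, bilayer_thickness=4.6,
                    defect_diameter_mean=200.0, defect_diameter_sd=60.0),
    # LB/LS DMPC:cholesterol on UPW: near-full coverage, slightly thicker
    "lbls_chol": dict(target_coverage=0.97, bilayer_thickness=4.7,
                      defect_diameter_mean=300.0, defect_diameter_sd=90.0),
    # vesicle fusion, 30 s: roughly half covered, coalescing-island morphology
    "vesicle_30s": dict(target_coverage=0.56, bilayer_thickness=4.7,
                        defect_diameter_mean=400.0, defect_diameter_sd=160.0,
                        allow_overlap=True),
    # vesicle fusion, 60 s: essentially covered bar small defects
    "vesicle_60s": dict(target_coverage=0.98, bilayer_thickness=4.6,
                        defect_diameter_mean=250.0, defect_diameter_sd=75.0),
    # vesicle fusion, 2 h: high coverage, rougher, deep (8.3 nm) pits appear
    "vesicle_2h": dict(target_coverage=0.95, bilayer_thickness=4.8,
                       defect_diameter_mean=300.0, defect_diameter_sd=90.0,
                       deep_defect_fraction=0.3, deep_defect_depth=8.3,
                       noise_sd=0.5),
    # blank substrate
    "bare": dict(target_coverage=0.0),
}

_default_seed = count()


def scene_presets(name: str, seed: int | None = None, **overrides) -> SyntheticScene:
    """A fully parameterized scene spec for a named deposition condition.

    ``seed`` defaults to a fresh value per call; pass one for reproducibility.
    Keyword overrides replace any spec field.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    if seed is None:
        seed = next(_default_seed)
    return SyntheticScene(seed=seed, **params)
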