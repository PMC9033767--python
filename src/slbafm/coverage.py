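"""Height thresholding and % surface-coverage measurement.

A flattened topograph of a partially deposited bilayer has a bimodal height
distribution: one mode for the bare substrate and one for the lipid terrace
roughly a bilayer thickness (~4.5 nm) above it.  Coverage is measured by
choosing a threshold between the modes, binarising (a pixel is covered iff
its height is strictly above the threshold) and counting covered pixels.

Threshold rules
---------------
valley     minimum of the Gaussian-smoothed height histogram between the two
           tallest peaks separated by at least ``min_separation`` (default,
           deterministic stand-in for manual profile inspection)
otsu       between-class variance maximiser (no bimodality requirement)
midpoint   arithmetic mean of the two peak positions
manual     caller-supplied value

Images whose histogram is unimodal (fully covered or bare — the two are
indistinguishable from topography alone) are flagged rather than silently
assigned; :func:`analyze_image` resolves the flag by comparing the single
mode's elevation above the scene floor with an expected bilayer-thickness
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu

from .preprocess import FlattenConfig, masked_flatten
from .raster_io import HeightMap

__all__ = [
    "CoverageResult",
    "NotBimodalError",
    "height_histogram",
    "determine_threshold",
    "binarize",
    "coverage_percent",
    "coverage_fraction_exact",
    "analyze_image",
]

THRESHOLD_METHODS = ("valley", "otsu", "midpoint", "manual")

#: default histogram bin width (nm); smoothing bandwidth is 2 bins
DEFAULT_BIN_WIDTH = 0.05
#: minimum peak separation (nm) for an automatic bimodal threshold
MIN_PEAK_SEPARATION = 1.0


class NotBimodalError(ValueError):
    """Raised when an automatic threshold rule needs two height modes."""


@dataclass
class CoverageResult:
    """Threshold, binary mask and % coverage for one image."""

    threshold: float
    mask: np.ndarray
    coverage_percent: float
    n_pixels: int
    histogram: tuple[np.ndarray, np.ndarray]
    method_used: str
    flags: tuple[str, ...] = ()
    flattened: HeightMap | None = field(default=None, repr=False)


def height_histogram(
    hmap: HeightMap | np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all pixel heights over uniform bins spanning [min, max].

    Returns ``(bin centres nm, counts)``; counts sum to the pixel count.  A
    constant map yields a single occupied bin.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    h = hmap.heights if isinstance(hmap, HeightMap) else np.asarray(hmap, float)
    lo, hi = float(h.min()), float(h.max())
    span = hi - lo
    if span == 0.0:
        return np.array([lo]), np.array([h.size])
    if bin_width > span:
        raise ValueError(f"bin_width {bin_width} exceeds height range {span:.4g} nm")
    n_bins = int(np.ceil(span / bin_width))
    counts, edges = np.histogram(h.ravel(), bins=n_bins, range=(lo, lo + n_bins * bin_width))
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, counts


def _smoothed_histogram(
    h: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    centres, counts = height_histogram(h, bin_width)
    if centres.size == 1:
        return centres, counts.astype(float)
    return centres, gaussian_filter1d(counts.astype(float), sigma=2.0)


def _two_modes(
    centres: np.ndarray, smoothed: np.ndarray, min_separation: float
) -> tuple[int, int]:
    """Indices of the two tallest smoothed-histogram peaks separated by at
    least ``min_separation`` nm; raises :class:`NotBimodalError` otherwise."""
    if centres.size < 3:
        raise NotBimodalError("not bimodal; supply manual threshold")
    total = float(smoothed.sum())
    # zero-pad so modes at the histogram ends count as peaks
    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = find_peaks(padded, prominence=max(2.0, 1e-4 * total))
    peaks -= 1
    if peaks.size < 2:
        raise NotBimodalError("not bimodal; supply manual threshold")
    order = np.argsort(smoothed[peaks])[::-1]
    primary = peaks[order[0]]
    for j in order[1:]:
        secondary = peaks[j]
        if abs(centres[secondary] - centres[primary]) >= min_separation:
            lo, hi = sorted((primary, secondary))
            return lo, hi
    raise NotBimodalError("not bimodal; supply manual threshold")


def determine_threshold(
    hmap: HeightMap | np.ndarray,
    method: str = "valley",
    manual_value: float | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_separation: float = MIN_PEAK_SEPARATION,
) -> float:
    """Choose the lipid/substrate height threshold (nm)."""
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"method must be one of {THRESHOLD_METHODS}")
    h = hmap.heights if isinstance(hmap, HeightMap) else np.asarray(hmap, float)
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual method requires manual_value")
        return float(manual_value)
    if method == "otsu":
        if h.min() == h.max():
            raise NotBimodalError("constant map; supply manual threshold")
        # between-class variance is flat across an empty inter-mode gap;
        # averaging the maximiser of h and of -h lands mid-plateau
        t_lo = float(threshold_otsu(h.ravel(), nbins=512))
        t_hi = -float(threshold_otsu(-h.ravel(), nbins=512))
        return 0.5 * (t_lo + t_hi)
    centres, smoothed = _smoothed_histogram(h, bin_width)
    i_lo, i_hi = _two_modes(centres, smoothed, min_separation)
    if method == "midpoint":
        return float(0.5 * (centres[i_lo] + centres[i_hi]))
    # valley: minimum of the smoothed histogram strictly between the peaks
    interior = slice(i_lo + 1, i_hi)
    valley = i_lo + 1 + int(np.argmin(smoothed[interior]))
    return float(centres[valley])


def binarize(hmap: HeightMap | np.ndarray, threshold: float) -> np.ndarray:
    """Covered ⇔ height strictly above the threshold; ties are uncovered."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    h = hmap.heights if isinstance(hmap, HeightMap) else np.asarray(hmap, float)
    return h > threshold


def coverage_fraction_exact(mask: np.ndarray) -> Fraction:
    """Covered fraction as an exact rational (covered pixels / all pixels)."""
    mask = np.asarray(mask, bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return Fraction(int(mask.sum()), int(mask.size))


def coverage_percent(mask: np.ndarray) -> float:
    """% coverage = 100 · covered/all, exact rational before float conversion."""
    return float(100 * coverage_fraction_exact(mask))


def analyze_image(
    hmap: HeightMap,
    flatten: FlattenConfig | None = None,
    threshold_method: str = "valley",
    manual_value: float | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    thickness_window: tuple[float, float] = (3.5, 5.5),
) -> CoverageResult:
    """Full single-image pipeline: flatten → threshold → binarise → count.

    A unimodal histogram (automatic methods only) is downgraded to a flagged
    result: if the single mode sits a bilayer thickness (``thickness_window``,
    nm, relative to the scene floor) above the lowest heights the image is
    taken as fully covered (100%), otherwise as bare (0%); the result carries
    the ``"unimodal"`` flag either way.
    """
    flatten = flatten or FlattenConfig()
    flat, _ = masked_flatten(hmap, flatten)
    h = flat.heights
    hist = height_histogram(h, bin_width) if h.min() < h.max() else height_histogram(h, 1.0)
    try:
        threshold = determine_threshold(
            flat, threshold_method, manual_value=manual_value, bin_width=bin_width
        )
    except NotBimodalError:
        centres, smoothed = (
            _smoothed_histogram(h, bin_width) if h.min() < h.max() else hist
        )
        mode = float(centres[int(np.argmax(smoothed))])
        floor = float(np.percentile(h, 0.5))  # robust scene minimum
        lo, hi = thickness_window
        if lo <= mode - floor <= hi:
            mask = np.ones_like(h, dtype=bool)
            threshold = float(h.min())
            flag = "unimodal-full"
        else:
            mask = np.zeros_like(h, dtype=bool)
            threshold = float(h.max())
            flag = "unimodal-bare"
        return CoverageResult(
            threshold=threshold,
            mask=mask,
            coverage_percent=coverage_percent(mask),
            n_pixels=h.size,
            histogram=hist,
            method_used=threshold_method,
            flags=("unimodal", flag),
            flattened=flat.with_heights(h, note=f"threshold flagged {flag}"),
        )
    mask = binarize(flat, threshold)
    return CoverageResult(
        threshold=threshold,
        mask=mask,
        coverage_percent=coverage_percent(mask),
        n_pixels=h.size,
        histogram=hist,
        method_used=threshold_method,
        flags=(),
        flattened=flat.with_heights(
            h, note=f"threshold={threshold:.3f} nm via {threshold_method}"
        ),
    )
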