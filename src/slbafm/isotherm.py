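"""Surface-pressure isotherm analysis for Langmuir monolayers.

Three computations on a π–A isotherm (surface pressure π in mN/m against
area per molecule A in Å², recorded along compression):

* :func:`limiting_area` — extrapolate the steepest (condensed) portion of
  the curve linearly to π = 0; the abscissa intercept A₀ is the limiting
  area per molecule.
* :func:`collapse_point` — the pressure/area at which the compressed film
  buckles, detected as the first slope break after the condensed region.
* :func:`transition_plateau` — an interior near-flat segment marking the
  liquid-expanded → liquid-condensed phase transition, or ``None`` when the
  film shows no such kink (e.g. cholesterol-rich mixtures, or above the
  chain-melting temperature).

Derivatives are taken as finite differences on the raw (A, π) sequence; no
smoothing is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Isotherm", "limiting_area", "collapse_point", "transition_plateau"]

MIN_POINTS = 10


@dataclass
class Isotherm:
    """A π–A compression isotherm.

    ``area`` (Å², strictly decreasing along compression) and ``pressure``
    (mN/m, non-negative) must have equal length ≥ 10.  Points supplied with
    increasing area are re-ordered into compression order.
    """

    area: np.ndarray
    pressure: np.ndarray
    temperature: float | None = None  # °C
    label: str = ""

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.area.shape != self.pressure.shape or self.area.ndim != 1:
            raise ValueError("area and pressure must be equal-length 1-D arrays")
        if self.area.size < MIN_POINTS:
            raise ValueError(f"too few points: {self.area.size} < {MIN_POINTS}")
        diffs = np.diff(self.area)
        if np.all(diffs > 0):  # supplied in expansion order
            self.area = self.area[::-1].copy()
            self.pressure = self.pressure[::-1].copy()
        elif not np.all(diffs < 0):
            raise ValueError("areas must be strictly monotone")
        if np.any(self.pressure < 0):
            raise ValueError("pressures must be >= 0")

    def __len__(self) -> int:
        return self.area.size


def _segment_slopes(iso: Isotherm) -> np.ndarray:
    """dπ/dA between consecutive points in compression order (typically < 0)."""
    return np.diff(iso.pressure) / np.diff(iso.area)


def _steep_window(iso: Isotherm, min_points: int = 5) -> tuple[int, int]:
    """Index range [i, j) of the steepest contiguous segment.

    The 5-point sliding window maximizing mean |dπ/dA| is found first, then
    extended on both sides while the local slope stays ≥ 80% of the maximum
    window slope.
    """
    slopes = np.abs(_segment_slopes(iso))
    w = min_points - 1  # segments per window
    if slopes.size < w:
        raise ValueError("isotherm too short for slope analysis")
    window_means = np.convolve(slopes, np.ones(w) / w, mode="valid")
    k = int(np.argmax(window_means))
    lo, hi = k, k + w  # segment index range
    threshold = 0.8 * window_means[k]
    while lo > 0 and slopes[lo - 1] >= threshold:
        lo -= 1
    while hi < slopes.size and slopes[hi] >= threshold:
        hi += 1
    return lo, hi + 1  # as point indices [lo, hi]


def limiting_area(
    iso: Isotherm, window: tuple[float, float] | None = None
) -> tuple[float, float, dict]:
    """Extrapolate the condensed region to π = 0.

    ``window`` optionally restricts the fit to a pressure range (mN/m);
    otherwise the steepest contiguous segment is used.  Returns
    ``(A₀ Å², slope mN m⁻¹ Å⁻², diagnostics)`` where A₀ is the abscissa
    intercept of the least-squares line π = s·(A₀ − A).
    """
    if window is not None:
        sel = (iso.pressure >= window[0]) & (iso.pressure <= window[1])
        if sel.sum() < 5:
            raise ValueError("fewer than 5 points inside the pressure window")
        A, P = iso.area[sel], iso.pressure[sel]
    else:
        lo, hi = _steep_window(iso)
        A, P = iso.area[lo : hi + 1], iso.pressure[lo : hi + 1]
    n = A.size
    design = np.stack([np.ones(n), A], axis=1)
    coeffs, residuals, *_ = np.linalg.lstsq(design, P, rcond=None)
    intercept, slope = coeffs
    dof = n - 2
    rss = float(residuals[0]) if residuals.size else float(np.sum((P - design @ coeffs) ** 2))
    se_slope = np.sqrt(rss / dof / np.sum((A - A.mean()) ** 2)) if dof > 0 else 0.0
    if se_slope > 0 and abs(slope) < 3 * se_slope:
        raise ValueError("no condensed region (slope not significant)")
    if slope == 0:
        raise ValueError("no condensed region (zero slope)")
    a0 = -intercept / slope
    diagnostics = {"n": int(n), "rss": rss, "se_slope": float(se_slope),
                   "area_range": (float(A.min()), float(A.max()))}
    return float(a0), float(slope), diagnostics


def collapse_point(iso: Isotherm) -> tuple[float, float]:
    """Pressure and area at monolayer collapse.

    Collapse is the first point, in compression order after the steep
    (condensed) region begins, where the segment slope changes sign or its
    magnitude drops below 20% of the condensed-region slope.
    """
    lo, hi = _steep_window(iso)
    slopes = _segment_slopes(iso)
    steep_slope = np.abs(slopes[lo : hi]).mean()
    steep_sign = np.sign(slopes[lo:hi].mean())
    for i in range(lo, len(iso) - 1):
        s = slopes[i]
        if np.sign(s) not in (steep_sign, 0.0) or abs(s) < 0.2 * steep_slope:
            return float(iso.pressure[i]), float(iso.area[i])
    raise ValueError("no collapse detected")


def transition_plateau(
    iso: Isotherm, slope_drop: float = 0.3
) -> tuple[float, tuple[float, float]] | None:
    """Detect an interior expanded→condensed phase-transition plateau.

    Looks for ≥ 3 consecutive points (≥ 2 segments) whose slope magnitude is
    below ``slope_drop`` × the median slope magnitude of the flanking
    segments, with non-empty steeper flanks on *both* sides (a plateau at the
    pressure maximum is a collapse, not a transition).  Returns
    ``(onset pressure mN/m, (A_min, A_max) Å²)`` or ``None``.
    """
    slopes = np.abs(_segment_slopes(iso))
    n_seg = slopes.size
    overall = np.median(slopes)
    if overall == 0:
        return None
    flat = slopes < slope_drop * overall
    # maximal runs of flat segments
    i = 0
    while i < n_seg:
        if not flat[i]:
            i += 1
            continue
        j = i
        while j < n_seg and flat[j]:
            j += 1
        run = slice(i, j)
        flank = np.concatenate([slopes[:i], slopes[j:]])
        interior = i > 0 and j < n_seg  # steeper segments on both sides
        if (
            j - i >= 2
            and interior
            and flank.size
            and np.all(slopes[run] < slope_drop * np.median(flank))
        ):
            onset = float(iso.pressure[i])
            a_span = (float(iso.area[j]), float(iso.area[i]))
            return onset, a_span
        i = j
    return None
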