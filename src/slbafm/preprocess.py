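"""Scanner-artifact removal: global polynomial background and per-line offsets.

Raster-scanned AFM topographs carry instrument artifacts that must be removed
before height thresholding: a global tilt between tip and sample plane (and
sometimes low-order bow from the piezo arc), plus per-scan-line DC offsets
from feedback drift.  The standard treatment — "flatten and plane-fit" — is
implemented here as a least-squares 2-D polynomial background subtraction
(:func:`plane_fit`) followed by per-row correction (:func:`line_flatten`).

Both operations accept an inclusion mask so that real surface features
(bilayer defects, multilayer islands, adsorbed vesicles) do not bias the
background estimate; :func:`masked_flatten` automates the iteration
flatten → identify the dominant terrace → re-flatten on terrace pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .raster_io import HeightMap

__all__ = ["FlattenConfig", "plane_fit", "line_flatten", "masked_flatten"]

LINE_METHODS = ("none", "median-offset", "per-line-polynomial")


@dataclass
class FlattenConfig:
    """Parameters of the flattening pipeline.

    plane_order
        Order of the global 2-D polynomial background (0–3); 1 removes tilt,
        2–3 remove scanner bow.
    line_method
        Per-row correction: ``none``, ``median-offset`` (subtract each row's
        median) or ``per-line-polynomial`` (subtract an order-``line_order``
        fit per row).
    mask_aware
        Iterate with exclusion of off-terrace pixels so defects and tall
        features do not bias the background fit.
    convergence_tol
        RMS change (nm) between iterates below which iteration stops.
    terrace_band_nm
        Half-width of the height band around the modal peak treated as the
        reference terrace during mask-aware iteration.
    """

    plane_order: int = 1
    line_method: str = "median-offset"
    line_order: int = 0
    mask_aware: bool = True
    max_iterations: int = 3
    convergence_tol: float = 0.01
    terrace_band_nm: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.plane_order <= 3:
            raise ValueError(f"plane_order must be in [0, 3], got {self.plane_order}")
        if self.line_method not in LINE_METHODS:
            raise ValueError(f"line_method must be one of {LINE_METHODS}")
        if not 0 <= self.line_order <= 2:
            raise ValueError(f"line_order must be in [0, 2], got {self.line_order}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.convergence_tol > 0:
            raise ValueError("convergence_tol must be > 0")


def _poly_terms(shape: tuple[int, int], order: int) -> np.ndarray:
    """Design matrix of 2-D monomials r^i c^j, i+j <= order, on [-1, 1] coords."""
    rows, cols = shape
    r = np.linspace(-1.0, 1.0, rows) if rows > 1 else np.zeros(rows)
    c = np.linspace(-1.0, 1.0, cols) if cols > 1 else np.zeros(cols)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    terms = [
        (rr**i) * (cc**j)
        for total in range(order + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.stack([t.ravel() for t in terms], axis=1)


def plane_fit(hmap: HeightMap, order: int, fit_mask: np.ndarray | None = None) -> HeightMap:
    """Subtract the least-squares 2-D polynomial background of given order.

    When ``fit_mask`` is given the polynomial is fitted on the masked (True)
    pixels only but subtracted everywhere.  The fitted background of the
    result is the zero polynomial to numerical precision.
    """
    if not 0 <= order <= 3:
        raise ValueError(f"order must be in [0, 3], got {order}")
    A = _poly_terms(hmap.shape, order)
    n_terms = A.shape[1]
    if hmap.n_pixels <= n_terms:
        raise ValueError("grid smaller than number of polynomial terms")
    b = hmap.heights.ravel()
    if fit_mask is not None:
        sel = np.asarray(fit_mask, bool).ravel()
        if sel.sum() <= n_terms:
            raise ValueError("too few unmasked pixels for the requested order")
        coeffs, _, rank, _ = np.linalg.lstsq(A[sel], b[sel], rcond=None)
    else:
        coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < n_terms:
        raise ValueError(f"degenerate background fit (rank {rank} < {n_terms} terms)")
    background = (A @ coeffs).reshape(hmap.shape)
    return hmap.with_heights(hmap.heights - background, note=f"plane_fit(order={order})")


def line_flatten(
    hmap: HeightMap,
    method: str = "median-offset",
    order: int = 0,
    mask: np.ndarray | None = None,
) -> HeightMap:
    """Per-scan-row correction; rows are processed independently.

    ``median-offset`` subtracts each row's median; ``per-line-polynomial``
    subtracts an order-``order`` least-squares fit per row.  With ``mask``
    (True = include in fit) every row must retain at least
    ``max(8, 3*(order+1))`` unmasked pixels.
    """
    if method not in LINE_METHODS:
        raise ValueError(f"method must be one of {LINE_METHODS}")
    if method == "none":
        return hmap.with_heights(hmap.heights.copy())
    h = hmap.heights.copy()
    rows, cols = h.shape
    x = np.linspace(-1.0, 1.0, cols)
    min_pixels = max(8, 3 * (order + 1))
    if mask is not None:
        mask = np.asarray(mask, bool)
        counts = mask.sum(axis=1)
        bad = np.flatnonzero(counts < min_pixels)
        if bad.size:
            raise ValueError(
                f"row {bad[0]} retains only {counts[bad[0]]} unmasked pixels "
                f"(need >= {min_pixels})"
            )
    for i in range(rows):
        sel = mask[i] if mask is not None else slice(None)
        if method == "median-offset":
            h[i] -= np.median(h[i][sel])
        else:
            coeffs = np.polynomial.polynomial.polyfit(
                x[sel] if mask is not None else x, h[i][sel], order
            )
            h[i] -= np.polynomial.polynomial.polyval(x, coeffs)
    return hmap.with_heights(h, note=f"line_flatten({method}, order={order})")


def _phase_modes(h: np.ndarray, bin_width: float = 0.05, min_separation: float = 1.0) -> np.ndarray:
    """Positions of up to two height modes (substrate / lipid terrace).

    The tallest peak of the Gaussian-smoothed histogram plus, when present,
    the tallest second peak at least ``min_separation`` nm away.
    """
    lo, hi = float(h.min()), float(h.max())
    if hi - lo < bin_width:
        return np.array([0.5 * (lo + hi)])
    n_bins = min(int(np.ceil((hi - lo) / bin_width)), 8192)
    counts, edges = np.histogram(h.ravel(), bins=n_bins, range=(lo, hi))
    smoothed = gaussian_filter1d(counts.astype(float), sigma=2.0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    from scipy.signal import find_peaks

    padded = np.concatenate([[0.0], smoothed, [0.0]])
    peaks, _ = find_peaks(padded, prominence=max(2.0, 1e-4 * float(smoothed.sum())))
    peaks -= 1
    if peaks.size == 0:
        return np.array([centres[int(np.argmax(smoothed))]])
    order = peaks[np.argsort(smoothed[peaks])[::-1]]
    modes = [centres[order[0]]]
    for idx in order[1:]:
        if abs(centres[idx] - modes[0]) >= min_separation:
            modes.append(centres[idx])
            break
    return np.asarray(sorted(modes))


def _terrace_mask(h: np.ndarray, band_nm: float) -> np.ndarray:
    """Pixels within ``band_nm`` of their nearest phase mode."""
    modes = _phase_modes(h)
    dist = np.min(np.abs(h[..., None] - modes[None, None, :]), axis=-1)
    return dist <= band_nm


def _fit_background(residual: np.ndarray, include: np.ndarray, config: FlattenConfig) -> np.ndarray:
    """Background (global polynomial + per-row correction) fitted to the
    mode-relative residuals over the included pixels, evaluated everywhere."""
    A = _poly_terms(residual.shape, config.plane_order)
    sel = include.ravel()
    coeffs, *_ = np.linalg.lstsq(A[sel], residual.ravel()[sel], rcond=None)
    background = (A @ coeffs).reshape(residual.shape)
    if config.line_method == "none":
        return background
    r = residual - background
    rows, cols = residual.shape
    x = np.linspace(-1.0, 1.0, cols)
    for i in range(rows):
        sel_i = include[i]
        if config.line_method == "median-offset":
            background[i] += np.median(r[i][sel_i])
        else:
            c = np.polynomial.polynomial.polyfit(x[sel_i], r[i][sel_i], config.line_order)
            background[i] += np.polynomial.polynomial.polyval(x, c)
    return background


def masked_flatten(hmap: HeightMap, config: FlattenConfig) -> tuple[HeightMap, np.ndarray]:
    """Feature-robust flattening.

    Iterates {flatten → locate the dominant terrace → re-flatten on terrace
    pixels only} until the flattened map changes by less than
    ``config.convergence_tol`` RMS or ``config.max_iterations`` is reached.
    Returns the flattened map and the final exclusion mask (True = pixel was
    excluded from the background fit).  Non-convergence is recorded as a
    warning in the map's provenance, never raised.
    """
    def _base_flatten(fit_mask: np.ndarray | None) -> HeightMap:
        out = plane_fit(hmap, config.plane_order, fit_mask=fit_mask)
        if config.line_method != "none":
            out = line_flatten(out, config.line_method, config.line_order, mask=fit_mask)
        return out

    exclusion = np.zeros(hmap.shape, dtype=bool)
    if not config.mask_aware:
        return _base_flatten(None), exclusion

    # initial estimate from the plane fit alone: an unmasked per-row
    # correction is bistable when neither phase dominates a row (rows get
    # referenced to whichever phase holds their median, splitting the modes)
    current = plane_fit(hmap, config.plane_order)

    min_pixels = max(8, 3 * (config.line_order + 1))
    converged = False
    for _ in range(config.max_iterations):
        h = current.heights
        modes = _phase_modes(h)
        # residual of each pixel to its nearest phase mode; pixels far from
        # every mode (defect walls, multilayers, vesicle caps) are excluded
        nearest = np.argmin(np.abs(h[..., None] - modes[None, None, :]), axis=-1)
        residual = h - modes[nearest]
        include = np.abs(residual) <= config.terrace_band_nm
        deficient = include.sum(axis=1) < min_pixels
        include[deficient, :] = True

        background = _fit_background(residual, include, config)
        new_h = h - background
        # heights are relative: convergence is judged modulo a constant shift
        rms = float(np.sqrt(np.mean((background - background.mean()) ** 2)))
        current = current.with_heights(new_h, note="masked_flatten iteration")
        exclusion = ~include
        if rms < config.convergence_tol:
            converged = True
            break
    if not converged:
        current = current.with_heights(
            current.heights,
            note=f"warning: masked_flatten did not converge in {config.max_iterations} iterations",
        )
    return current, exclusion
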