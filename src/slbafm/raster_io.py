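"""Calibrated height-raster and batch-manifest I/O.

All downstream analysis consumes :class:`HeightMap` objects produced here.
On disk a height map is a 32-bit float TIFF accompanied by a structured-text
(YAML) sidecar carrying the lateral calibration and provenance, or a plain
text matrix with ``# key: value`` header lines.  Heights are always converted
to nanometres on read; the height origin is arbitrary (only differences are
meaningful).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "HeightMap",
    "Manifest",
    "ManifestEntry",
    "read_heightmap",
    "write_heightmap",
    "read_manifest",
    "write_mask",
]

#: multiplicative factors converting a height unit to nanometres
UNIT_TO_NM = {"m": 1e9, "um": 1e3, "µm": 1e3, "nm": 1.0}

MIN_GRID = 8


@dataclass
class HeightMap:
    """A calibrated 2-D topograph.

    Parameters
    ----------
    heights
        Rectangular grid of surface heights in nm, row 0 = top scan line,
        column 0 = left, pixel centres at integer (row, col) coordinates.
        Heights are relative: only differences carry meaning.
    pixel_size
        Isotropic lateral calibration in nm per pixel (> 0).
    name
        Identifier used in tables and file names.
    provenance
        Free-text acquisition / processing notes, appended to by the
        processing stages.
    """

    heights: np.ndarray
    pixel_size: float
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise ValueError(f"heights must be 2-D, got {self.heights.ndim}-D")
        if min(self.heights.shape) < MIN_GRID:
            raise ValueError(
                f"grid must be at least {MIN_GRID}x{MIN_GRID}, got {self.heights.shape}"
            )
        bad = ~np.isfinite(self.heights)
        if bad.any():
            idx = np.argwhere(bad)[:10]
            raise ValueError(
                f"non-finite heights at (row, col) indices {idx.tolist()}"
                + (" ..." if bad.sum() > 10 else "")
            )
        self.pixel_size = float(self.pixel_size)
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def n_pixels(self) -> int:
        return self.heights.size

    def with_heights(self, heights: np.ndarray, note: str = "") -> "HeightMap":
        """Copy of this map with new heights and an optional provenance note."""
        prov = self.provenance
        if note:
            prov = f"{prov}; {note}" if prov else note
        return dataclasses.replace(self, heights=np.asarray(heights, float), provenance=prov)


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    condition: str
    path: Path


@dataclass
class Manifest:
    """Batch listing mapping samples (and their condition labels) to images."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest has no entries")
        seen = set()
        for e in self.entries:
            if not e.sample_id:
                raise ValueError("empty sample_id in manifest")
            key = (e.sample_id, str(e.path))
            if key in seen:
                raise ValueError(f"duplicate (sample, path) row: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        out: list[str] = []
        for e in self.entries:
            if e.condition not in out:
                out.append(e.condition)
        return out


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _heights_to_nm(values: np.ndarray, unit: str, source: str) -> np.ndarray:
    try:
        factor = UNIT_TO_NM[unit]
    except KeyError:
        raise ValueError(
            f"{source}: unknown height unit {unit!r} (expected one of {sorted(UNIT_TO_NM)})"
        ) from None
    return values * factor


def read_heightmap(path: str | Path, format: str | None = None) -> HeightMap:
    """Read a calibrated height raster.

    ``format`` is ``"float-tiff"`` or ``"text-matrix"``; when omitted it is
    inferred from the suffix (``.tif``/``.tiff`` vs anything else).  Missing
    calibration (``pixel_size_nm``) or height unit is a hard error — there is
    no silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "float-tiff" if path.suffix.lower() in {".tif", ".tiff"} else "text-matrix"

    if format == "float-tiff":
        heights = np.asarray(tifffile.imread(path), dtype=np.float64)
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"missing metadata sidecar for {path}: {sidecar}")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    elif format == "text-matrix":
        meta = {}
        data_lines: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.lstrip().startswith("#"):
                    body = line.lstrip()[1:].strip()
                    if ":" in body:
                        key, _, value = body.partition(":")
                        meta[key.strip()] = value.strip()
                elif line.strip():
                    data_lines.append(line)
        if not data_lines:
            raise ValueError(f"{path}: no matrix data")
        heights = np.loadtxt(data_lines, dtype=np.float64)
        heights = np.atleast_2d(heights)
    else:
        raise ValueError(f"unknown format {format!r}")

    if "pixel_size_nm" not in meta:
        raise ValueError(f"{path}: missing calibration key 'pixel_size_nm' — refusing to guess")
    if "unit" not in meta:
        raise ValueError(f"{path}: missing height 'unit' — refusing to guess")
    pixel_size = float(meta["pixel_size_nm"])
    heights = _heights_to_nm(heights, str(meta["unit"]), str(path))
    return HeightMap(
        heights=heights,
        pixel_size=pixel_size,
        name=str(meta.get("name", path.stem)),
        provenance=str(meta.get("provenance", "")),
    )


def write_heightmap(hmap: HeightMap, path: str | Path) -> Path:
    """Write a 32-bit float TIFF plus YAML sidecar; round-trips with
    :func:`read_heightmap` to float-32 precision."""
    path = Path(path)
    tifffile.imwrite(path, hmap.heights.astype(np.float32))
    meta = {
        "pixel_size_nm": hmap.pixel_size,
        "unit": "nm",
        "name": hmap.name,
        "provenance": hmap.provenance,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit raster (covered = 255)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


REQUIRED_MANIFEST_COLUMNS = ("sample_id", "condition", "path")


def read_manifest(path: str | Path) -> Manifest:
    """Read a delimited-text (tab or comma) manifest with a header row.

    Relative image paths are resolved against the manifest's directory.
    Duplicate (sample, path) rows and unresolvable paths are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no entries") from None
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no entries")
    entries = []
    for i, row in df.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = (path.parent / p).resolve()
        if not p.exists():
            raise FileNotFoundError(
                f"{path} row {i}: sample {row['sample_id']!r} references missing file {p}"
            )
        entries.append(
            ManifestEntry(sample_id=str(row["sample_id"]), condition=str(row["condition"]), path=p)
        )
    return Manifest(entries=entries)
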