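"""FLIM data model and on-disk formats.

A FLIM frame pairs a photon-count (intensity) image with a co-registered
fluorescence-lifetime matrix in picoseconds.  Lifetimes exist only where
enough photons were collected for a decay fit; a boolean validity mask
records which pixels carry a meaningful lifetime, and every downstream
computation must ignore invalid pixels.

On disk: intensity is a single-channel TIFF (or a whitespace-delimited
text matrix); the lifetime matrix is a whitespace-delimited ASCII matrix
in the style of SPCImage-type exports, where values <= 0 (or non-finite)
mean "no fitted lifetime"; the mask is an 8-bit grayscale PNG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "IntensityImage",
    "LifetimeImage",
    "FLIMFrame",
    "read_intensity",
    "read_lifetime_asc",
    "make_mask",
    "write_frame",
    "read_frame",
]


@dataclass
class IntensityImage:
    """2-D grid of nonnegative photon counts."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"intensity must be 2-D, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("intensity contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LifetimeImage:
    """2-D grid of fitted lifetimes in picoseconds with a validity mask.

    ``valid=False`` pixels carry no meaningful lifetime and must not
    influence any computation; ``valid=True`` pixels have values > 0.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError(f"lifetime must be 2-D, got shape {self.values.shape}")
        if self.values.shape != self.valid.shape:
            raise ValueError("lifetime values and validity mask shapes differ")
        if np.any(self.values[self.valid] <= 0) or not np.all(
            np.isfinite(self.values[self.valid])
        ):
            raise ValueError("valid lifetime pixels must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FLIMFrame:
    """Co-registered intensity + lifetime pair with acquisition metadata."""

    intensity: IntensityImage
    lifetime: LifetimeImage
    photon_threshold: float = 0.0
    pixel_size_um: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.shape != self.lifetime.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != lifetime shape {self.lifetime.shape}"
            )
        if self.photon_threshold < 0:
            raise ValueError("photon_threshold must be >= 0")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


def read_intensity(path: str | Path, format: str | None = None) -> IntensityImage:
    """Read a single-channel intensity image from TIFF or a text matrix.

    ``format`` is ``"tiff"`` or ``"text"``; if omitted it is inferred from
    the file suffix (``.tif``/``.tiff`` -> tiff, otherwise text).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"intensity file not found: {path}")
    if format is None:
        format = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "text"
    if format == "tiff":
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"expected single-channel 2-D TIFF, got shape {arr.shape}")
        values = arr.astype(float)
    elif format == "text":
        values = _parse_text_matrix(path)
    else:
        raise ValueError(f"unknown intensity format: {format!r}")
    if np.any(values < 0):
        raise ValueError(f"negative intensity value in {path}")
    return IntensityImage(values)


def _parse_text_matrix(path: Path, skip_header: bool = False) -> np.ndarray:
    rows: list[list[float]] = []
    in_header = skip_header
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            row = [float(t) for t in tokens]
        except ValueError:
            if in_header and not rows:
                continue  # vendor exports may carry leading text lines
            raise ValueError(f"non-numeric token in {path} at line {lineno}") from None
        in_header = False
        rows.append(row)
    if not rows:
        raise ValueError(f"empty matrix in {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"ragged matrix in {path}: row widths {sorted(widths)}")
    return np.array(rows, dtype=float)


def read_lifetime_asc(path: str | Path) -> LifetimeImage:
    """Read an SPCImage-style ASCII lifetime matrix (picoseconds).

    Leading lines that do not parse as numbers are skipped as a header.
    Values <= 0 or non-finite are the "no fitted lifetime" sentinel and
    become invalid pixels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lifetime file not found: {path}")
    values = _parse_text_matrix(path, skip_header=True)
    valid = np.isfinite(values) & (values > 0)
    return LifetimeImage(np.where(valid, values, 0.0), valid)


def make_mask(intensity: IntensityImage, photon_threshold: float) -> np.ndarray:
    """Boolean mask, true exactly where the photon count reaches the threshold.

    Lifetime fitting needs a minimum number of photons; below the threshold
    no lifetime is defined and the pixel must be excluded from interpolation.
    """
    if photon_threshold < 0:
        raise ValueError("photon_threshold must be >= 0")
    return np.asarray(intensity.values >= photon_threshold)


_LIFETIME_FMT = "%.6g"  # below any meaningful lifetime-fitting precision


def write_frame(frame: FLIMFrame, out_prefix: str | Path) -> dict[str, Path]:
    """Write a frame as <prefix>_intensity.tiff, _lifetime.asc, _mask.png, _meta.json.

    Invalid lifetime pixels are written as 0.  Reading the files back
    reproduces the intensity bit-exactly and the lifetime to the printed
    precision (6 significant digits).
    """
    out_prefix = Path(out_prefix)
    if frame.intensity.shape != frame.lifetime.shape:  # defensive; dataclass enforces it
        raise ValueError("frame shapes inconsistent")
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensity": out_prefix.with_name(out_prefix.name + "_intensity.tiff"),
        "lifetime": out_prefix.with_name(out_prefix.name + "_lifetime.asc"),
        "mask": out_prefix.with_name(out_prefix.name + "_mask.png"),
        "meta": out_prefix.with_name(out_prefix.name + "_meta.json"),
    }
    tifffile.imwrite(paths["intensity"], frame.intensity.values)
    tau = np.where(frame.lifetime.valid, frame.lifetime.values, 0.0)
    np.savetxt(paths["lifetime"], tau, fmt=_LIFETIME_FMT)
    iio.imwrite(paths["mask"], (frame.lifetime.valid * 255).astype(np.uint8))
    meta = dict(frame.meta)
    meta.update(
        photon_threshold=frame.photon_threshold,
        pixel_size_um=frame.pixel_size_um,
    )
    paths["meta"].write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return paths


def read_frame(prefix: str | Path) -> FLIMFrame:
    """Read back a frame written by :func:`write_frame`."""
    prefix = Path(prefix)
    intensity = read_intensity(prefix.with_name(prefix.name + "_intensity.tiff"))
    lifetime = read_lifetime_asc(prefix.with_name(prefix.name + "_lifetime.asc"))
    meta_path = prefix.with_name(prefix.name + "_meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    threshold = float(meta.pop("photon_threshold", 0.0))
    pixel_size = meta.pop("pixel_size_um", None)
    return FLIMFrame(
        intensity=intensity,
        lifetime=lifetime,
        photon_threshold=threshold,
        pixel_size_um=float(pixel_size) if pixel_size is not None else None,
        meta=meta,
    )
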