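"""Pseudo-color composition of intensity and lifetime into one RGB image.

Each pixel's lifetime selects a hue from an explicit lookup table
(by default 256 bins sweeping hue 0 deg -> 240 deg, i.e. red for short
lifetimes through blue for long ones, at full saturation) and the
photon count scales the brightness.  Pixels without a fitted lifetime
render black.  This is the conventional FLIM display: structure from
intensity, photophysics from hue.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from matplotlib.colors import hsv_to_rgb

from .flimio import LifetimeImage

__all__ = ["ColorSpec", "build_lut", "compose", "write_png"]


@dataclass
class ColorSpec:
    """Lifetime-to-hue encoding parameters.

    tau_min/tau_max bound the displayed lifetime range in picoseconds;
    lifetimes outside clamp to the end bins.  intensity_clip_percentile
    sets the photon count mapped to full brightness (a high percentile
    rather than the max, for robustness to hot pixels).
    """

    tau_min: float = 700.0
    tau_max: float = 1400.0
    n_bins: int = 256
    invert: bool = False
    intensity_clip_percentile: float = 99.5

    def __post_init__(self) -> None:
        if self.tau_min >= self.tau_max:
            raise ValueError("tau_min must be < tau_max")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0 < self.intensity_clip_percentile <= 100):
            raise ValueError("intensity_clip_percentile must lie in (0, 100]")

    @property
    def bin_width(self) -> float:
        return (self.tau_max - self.tau_min) / self.n_bins


def build_lut(spec: ColorSpec) -> np.ndarray:
    """(n_bins, 3) float RGB table; bin k covers [tau_min + k*d, tau_min + (k+1)*d)."""
    hue = np.linspace(0.0, 240.0 / 360.0, spec.n_bins)
    hsv = np.stack([hue, np.ones_like(hue), np.ones_like(hue)], axis=-1)
    lut = hsv_to_rgb(hsv)
    if spec.invert:
        lut = lut[::-1]
    return lut


def compose(intensity: np.ndarray, lifetime: LifetimeImage, spec: ColorSpec) -> np.ndarray:
    """8-bit RGB image: hue from the lifetime bin, brightness from intensity."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != lifetime.shape:
        raise ValueError(
            f"intensity shape {intensity.shape} != lifetime shape {lifetime.shape}"
        )
    lut = build_lut(spec)
    bins = np.floor((lifetime.values - spec.tau_min) / spec.bin_width).astype(int)
    bins = np.clip(bins, 0, spec.n_bins - 1)
    scale = np.percentile(intensity, spec.intensity_clip_percentile)
    brightness = np.clip(intensity / scale, 0.0, 1.0) if scale > 0 else np.zeros_like(intensity)
    rgb = lut[bins] * brightness[..., None]
    rgb[~lifetime.valid] = 0.0
    return np.round(rgb * 255.0).astype(np.uint8)


def write_png(rgb: np.ndarray, path: str | Path, spec: ColorSpec | None = None) -> None:
    """Write the rendered image; optional side-car JSON records the ColorSpec."""
    path = Path(path)
    iio.imwrite(path, rgb)
    if spec is not None:
        path.with_suffix(".colorspec.json").write_text(
            json.dumps(asdict(spec), indent=2, sort_keys=True)
        )
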