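"""Bicubic (cubic-convolution) interpolation of intensity and masked lifetime grids.

The interpolated value at a fractional position (i+s, j+t) is the
separable weighted sum A.B.C over the 4x4 neighborhood of known pixels,
where A and C hold the cubic kernel weights at the four row/column
distances (1+s, s, 1-s, 2-s) and B is the 4x4 sample block.  The kernel
is the standard one-parameter cubic-convolution family

    R(x) = (a+2)|x|^3 - (a+3)|x|^2 + 1          0 <= |x| < 1
         = a|x|^3 - 5a|x|^2 + 8a|x| - 4a        1 <= |x| < 2
         = 0                                    |x| >= 2

with a = -1 by default (R(x) = 1 - 2x^2 + x^3 on [0,1) and
4 - 8x + 5x^2 - x^3 on [1,2)).  The weights form a partition of unity,
so constants are reproduced exactly; a = -1 additionally reproduces
affine images exactly.

For lifetime matrices, pixels without a fitted lifetime contribute
neither value nor weight: surviving weights are renormalized to sum to
1, and the output pixel is marked invalid when too little of the stencil
survives (absolute surviving weight mass below ``min_support``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flimio import LifetimeImage

__all__ = [
    "kernel_weight",
    "interpolate_at",
    "bicubic_upscale",
    "masked_bicubic_upscale",
    "UpscaleResult",
]

DEFAULT_A = -1.0
DEFAULT_MIN_SUPPORT = 0.5


@dataclass
class UpscaleResult:
    """Interpolated grid at target resolution plus a validity mask."""

    values: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def kernel_weight(x, a: float = DEFAULT_A):
    """Cubic-convolution kernel weight R(x) at distance x >= 0.

    Vectorized over x.  Continuous at the branch points: R(0)=1, R(2)=0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("kernel distance must be >= 0")
    near = (a + 2.0) * x**3 - (a + 3.0) * x**2 + 1.0
    far = a * x**3 - 5.0 * a * x**2 + 8.0 * a * x - 4.0 * a
    out = np.where(x < 1.0, near, np.where(x < 2.0, far, 0.0))
    return out if out.ndim else float(out)


def _offset_weights(s: float, a: float) -> np.ndarray:
    """Kernel weights at the 4 integer samples bracketing fractional offset s."""
    return kernel_weight(np.array([1.0 + s, s, 1.0 - s, 2.0 - s]), a)


def interpolate_at(
    source: np.ndarray, i: int, j: int, s: float, t: float, a: float = DEFAULT_A
) -> float:
    """Value at (i+s, j+t) from the 4x4 block rows i-1..i+2, cols j-1..j+2.

    The source is edge-replicated, so the block exists for any (i, j)
    inside the image.
    """
    if not (0.0 <= s < 1.0 and 0.0 <= t < 1.0):
        raise ValueError("fractional offsets s, t must lie in [0, 1)")
    source = np.asarray(source, dtype=float)
    rows = np.clip(np.arange(i - 1, i + 3), 0, source.shape[0] - 1)
    cols = np.clip(np.arange(j - 1, j + 3), 0, source.shape[1] - 1)
    block = source[np.ix_(rows, cols)]
    A = _offset_weights(s, a)
    C = _offset_weights(t, a)
    return float(A @ block @ C)


def _check_factor(factor: int) -> None:
    if factor not in (2, 4):
        raise ValueError(f"unsupported upscale factor {factor}; expected 2 or 4")


def _shifted(padded: np.ndarray, m: int, n: int, R: int, C: int) -> np.ndarray:
    # padded has 1 extra row/col at top/left, 2 at bottom/right; (m, n) in 0..3
    return padded[m : m + R, n : n + C]


def bicubic_upscale(image: np.ndarray, factor: int, a: float = DEFAULT_A) -> UpscaleResult:
    """Upscale a 2-D grid by 2x or 4x with separable cubic convolution.

    Source pixel (i, j) maps to output (factor*i, factor*j) (0-based), so
    source values reappear bit-exactly at those positions and the output
    is registered pixel-for-pixel with the edge-preserving interpolator.
    """
    _check_factor(factor)
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 4:
        raise ValueError("image must be 2-D and at least 4x4")
    R, C = image.shape
    padded = np.pad(image, ((1, 2), (1, 2)), mode="edge")
    out = np.empty((factor * R, factor * C), dtype=float)
    for dr in range(factor):
        s = dr / factor
        A = _offset_weights(s, a)
        for dc in range(factor):
            t = dc / factor
            Cw = _offset_weights(t, a)
            if dr == 0 and dc == 0:
                out[::factor, ::factor] = image  # exact copy, no arithmetic
                continue
            acc = np.zeros((R, C))
            for m in range(4):
                if A[m] == 0.0:
                    continue
                for n in range(4):
                    w = A[m] * Cw[n]
                    if w == 0.0:
                        continue
                    acc += w * _shifted(padded, m, n, R, C)
            out[dr::factor, dc::factor] = acc
    return UpscaleResult(out, np.ones_like(out, dtype=bool))


def masked_bicubic_upscale(
    lifetime: LifetimeImage,
    factor: int,
    a: float = DEFAULT_A,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> UpscaleResult:
    """Bicubic upscaling of a lifetime matrix that ignores unfitted pixels.

    Masked source pixels contribute neither value nor weight; the
    surviving weights are renormalized to sum to 1.  An output pixel is
    invalid when the surviving absolute weight mass falls below
    ``min_support`` (refuse to fabricate lifetimes from a mostly-missing
    stencil) or when the signed weight sum degenerates.
    """
    _check_factor(factor)
    if not (0.0 < min_support <= 1.0):
        raise ValueError("min_support must lie in (0, 1]")
    values = np.asarray(lifetime.values, dtype=float)
    valid = np.asarray(lifetime.valid, dtype=bool)
    if values.ndim != 2 or min(values.shape) < 4:
        raise ValueError("lifetime must be 2-D and at least 4x4")
    if not valid.any():
        raise ValueError("all-masked lifetime input")
    R, C = values.shape
    vpad = np.pad(np.where(valid, values, 0.0), ((1, 2), (1, 2)), mode="edge")
    mpad = np.pad(valid.astype(float), ((1, 2), (1, 2)), mode="edge")
    out = np.empty((factor * R, factor * C), dtype=float)
    out_valid = np.empty((factor * R, factor * C), dtype=bool)
    for dr in range(factor):
        A = _offset_weights(dr / factor, a)
        for dc in range(factor):
            Cw = _offset_weights(dc / factor, a)
            if dr == 0 and dc == 0:
                out[::factor, ::factor] = np.where(valid, values, 0.0)
                out_valid[::factor, ::factor] = valid
                continue
            num = np.zeros((R, C))
            den = np.zeros((R, C))
            absmass = np.zeros((R, C))
            for m in range(4):
                for n in range(4):
                    w = A[m] * Cw[n]
                    if w == 0.0:
                        continue
                    mk = _shifted(mpad, m, n, R, C)
                    num += w * _shifted(vpad, m, n, R, C)
                    den += w * mk
                    absmass += abs(w) * mk
            ok = (absmass >= min_support) & (np.abs(den) > 1e-9)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
            out[dr::factor, dc::factor] = vals
            out_valid[dr::factor, dc::factor] = ok
    return UpscaleResult(out, out_valid)
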